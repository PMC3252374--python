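"""Repeat annotation: RepeatMasker parsing, family classification, and
assignment of genome hits to repeat copies.

A hit is "in" a repeat only when fully contained in the repeat interval;
a hit overlapping but not contained is flagged ``partial`` and counted as
outside in all census tables (accessible-chromatin overlap elsewhere uses
the different >=1-nt rule on purpose). When several annotated features
contain one hit (nested or overlapping annotation), the owner is the
feature with the smallest start, then smallest end, and the hit is flagged
ambiguous.

Consensus coordinates are 1-based inclusive positions within the repeat
subfamily's consensus sequence, exactly as RepeatMasker reports them; all
genomic coordinates are 0-based half-open internally and converted only at
the ``.out`` file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .scan import GenomeHit

ALU_FAMILY_CLASSES = ("AluY", "AluS", "AluJ", "FRAM", "FLAM_A", "FLAM_C", "FAM")
_EXACT_CLASSES = frozenset(("FLAM_A", "FLAM_C", "FRAM", "FAM"))


def classify_family(subfamily: str) -> str:
    """Deterministic family class of a repeat subfamily name.

    Prefix rules AluY*/AluS*/AluJ* plus the exact monomer families
    (FLAM_A, FLAM_C, FRAM, FAM); everything else is ``other_named`` and
    keeps its subfamily name for non-Alu reporting (Tigger2a, MIRb, ...).
    """
    if not subfamily:
        raise ValueError("empty subfamily name")
    for prefix in ("AluY", "AluS", "AluJ"):
        if subfamily.startswith(prefix):
            return prefix
    if subfamily in _EXACT_CLASSES:
        return subfamily
    return "other_named"


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated repeat copy."""

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_begin: int
    consensus_end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate repeat interval {self.start}..{self.end}")

    @property
    def family_class(self) -> str:
        return classify_family(self.subfamily)

    @property
    def is_alu(self) -> bool:
        return self.family_class in ALU_FAMILY_CLASSES

    @property
    def key(self) -> Tuple[str, int, int, str]:
        """Stable identity of this repeat copy."""
        return (self.chrom, self.start, self.end, self.subfamily)


def parse_repeatmasker_out(path) -> List[RepeatFeature]:
    """Parse the 15-column RepeatMasker ``.out`` dialect (3-line header).

    Genomic begin/end are 1-based inclusive in the file and converted to
    0-based half-open. Strand ``C`` means minus; its consensus columns are
    laid out ``(left) end begin`` and are decoded back to begin <= end.
    """
    features = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 14:
                raise ValueError(f"{path}:{lineno}: expected >=14 columns, got {len(fields)}")
            try:
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand_sym = fields[8]
                subfamily = fields[9]
                if strand_sym == "+":
                    strand = "+"
                    consensus_begin = int(fields[11])
                    consensus_end = int(fields[12])
                elif strand_sym in ("C", "-"):
                    strand = "-"
                    consensus_end = int(fields[12])
                    consensus_begin = int(fields[13])
                else:
                    raise ValueError(f"unknown strand symbol {strand_sym!r}")
                features.append(RepeatFeature(chrom, start, end, strand, subfamily,
                                              consensus_begin, consensus_end))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    return features


_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def write_repeatmasker_out(features: Sequence[RepeatFeature], path) -> None:
    """Write features in the ``.out`` dialect (synthetic score/divergence 0)."""
    with open(path, "w") as handle:
        handle.write(_OUT_HEADER)
        for i, f in enumerate(features, start=1):
            if f.strand == "+":
                rep_cols = f"{f.consensus_begin}  {f.consensus_end}  (0)"
                strand_sym = "+"
            else:
                rep_cols = f"(0)  {f.consensus_end}  {f.consensus_begin}"
                strand_sym = "C"
            handle.write(
                f"  0  0.0  0.0  0.0  {f.chrom}  {f.start + 1}  {f.end}  (0)  "
                f"{strand_sym}  {f.subfamily}  SINE/Alu  {rep_cols}  {i}\n"
            )


def features_from_bed(frame: pd.DataFrame) -> List[RepeatFeature]:
    """RepeatFeatures from a BED6 frame (name column = subfamily).

    BED carries no consensus offsets, so copies are assumed full-length
    from consensus position 1.
    """
    out = []
    for r in frame.itertuples(index=False):
        length = int(r.end) - int(r.start)
        out.append(RepeatFeature(r.chrom, int(r.start), int(r.end), r.strand,
                                 str(r.name), 1, length))
    return out


def features_to_bed(features: Sequence[RepeatFeature]) -> pd.DataFrame:
    rows = [(f.chrom, f.start, f.end, f.subfamily, 0, f.strand) for f in features]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def consensus_position(hit: GenomeHit, repeat: RepeatFeature) -> int:
    """1-based consensus coordinate of the hit start within the repeat.

    On the minus strand the repeat's genomic end corresponds to consensus
    position ``consensus_begin``, so the position is mirrored.
    """
    if not (repeat.start <= hit.start and hit.end <= repeat.end):
        raise ValueError("consensus_position requires a fully contained hit")
    if repeat.strand == "+":
        return repeat.consensus_begin + (hit.start - repeat.start)
    return repeat.consensus_begin + (repeat.end - hit.end)


@dataclass(frozen=True)
class AnnotatedHit:
    hit: GenomeHit
    repeat: Optional[RepeatFeature]
    containment: str  # contained | partial | outside
    consensus_position: Optional[int] = None
    ambiguous: bool = False

    def __post_init__(self):
        if (self.containment == "contained") != (self.consensus_position is not None):
            raise ValueError("consensus_position defined iff containment == contained")


def assign_hits(hits: Iterable[GenomeHit],
                repeats: Sequence[RepeatFeature]) -> List[AnnotatedHit]:
    """Assign each hit to at most one owning repeat copy.

    contained: hit interval fully inside the repeat interval;
    partial: overlapping but not contained (treated as outside by census);
    outside: no overlap. Multiple containing features resolve to the one
    with smallest (start, end); the hit is then flagged ambiguous.
    """
    trees: Dict[str, IntervalTree] = {}
    for idx, feature in enumerate(repeats):
        trees.setdefault(feature.chrom, IntervalTree()).addi(feature.start, feature.end, idx)
    annotated = []
    for hit in hits:
        tree = trees.get(hit.chrom)
        overlapping = sorted(tree.overlap(hit.start, hit.end),
                             key=lambda iv: (iv.begin, iv.end)) if tree else []
        containing = [iv for iv in overlapping
                      if iv.begin <= hit.start and hit.end <= iv.end]
        if containing:
            owner = repeats[containing[0].data]
            annotated.append(AnnotatedHit(
                hit=hit, repeat=owner, containment="contained",
                consensus_position=consensus_position(hit, owner),
                ambiguous=len(containing) > 1))
        elif overlapping:
            annotated.append(AnnotatedHit(hit=hit, repeat=repeats[overlapping[0].data],
                                          containment="partial"))
        else:
            annotated.append(AnnotatedHit(hit=hit, repeat=None, containment="outside"))
    return annotated


def annotated_hits_to_frame(annotated: Sequence[AnnotatedHit]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        rows.append((a.hit.chrom, a.hit.start, a.hit.end, a.hit.strand, a.hit.kmer_id,
                     a.containment,
                     a.repeat.subfamily if a.repeat else "",
                     a.repeat.family_class if a.repeat else "",
                     a.repeat.start if a.repeat else "",
                     a.repeat.end if a.repeat else "",
                     a.consensus_position if a.consensus_position is not None else "",
                     a.ambiguous))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "kmer_id",
                                       "containment", "subfamily", "family_class",
                                       "repeat_start", "repeat_end",
                                       "consensus_position", "ambiguous"])
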