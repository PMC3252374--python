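"""Exact multi-pattern k-mer search over genome sequences.

Every exact occurrence of every query k-mer is reported, overlapping
occurrences included. The scanner is a single pass per pattern length: all
patterns of one length are held in a hash map keyed by window sequence (and,
in both-strands mode, by reverse complement), so scanning is O(genome x
number of distinct pattern lengths) regardless of how many patterns there
are. Soft-masked (lowercase) genome bases match after uppercasing; ``N`` and
other ambiguity codes never match because only A/C/G/T patterns are admitted
to the lookup.

Strand semantics in ``both`` mode: a locus whose forward sequence equals
pattern P yields a plus-strand hit for P; a locus whose reverse complement
equals P yields a minus-strand hit for P. A reverse-complement palindrome
therefore yields a single plus-strand hit (the canonical orientation), not
two.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeHit:
    """One exact occurrence of a query k-mer in the genome.

    Coordinates are 0-based half-open. On the minus strand,
    ``reverse_complement(genome[start:end])`` equals the k-mer.
    """

    chrom: str
    start: int
    end: int
    strand: str
    kmer_id: str


def _pattern_map(kmer_set: Mapping[str, str] | Iterable[str],
                 strands: str) -> Dict[int, Dict[str, List[Tuple[str, str]]]]:
    """Build per-length window -> [(kmer_id, strand)] lookup tables."""
    if isinstance(kmer_set, Mapping):
        items = list(kmer_set.items())
    else:
        items = [(k, k) for k in kmer_set]
    if not items:
        raise ValueError("empty k-mer set")
    by_len: Dict[int, Dict[str, List[Tuple[str, str]]]] = {}
    for kmer_id, seq in items:
        if not seq or set(seq) - _VALID:
            raise ValueError(f"k-mer {kmer_id!r} contains non-ACGT characters: {seq!r}")
        table = by_len.setdefault(len(seq), {})
        table.setdefault(seq, []).append((kmer_id, "+"))
        if strands == "both":
            rc = reverse_complement(seq)
            if rc != seq:  # palindromes collapse to the canonical + hit
                table.setdefault(rc, []).append((kmer_id, "-"))
    for table in by_len.values():
        for entries in table.values():
            entries.sort()
    return by_len


def scan(genome: Mapping[str, str],
         kmer_set: Mapping[str, str] | Iterable[str],
         strands: str = "both") -> List[GenomeHit]:
    """Find all exact occurrences of the k-mers in ``genome``.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence. May contain N or lowercase
        (soft-masked) bases; lowercase matches, N never does.
    kmer_set
        Either an iterable of k-mer strings (each its own id) or a mapping
        of id -> k-mer sequence. Patterns must be uppercase A/C/G/T.
    strands
        ``"both"`` (default) or ``"plus_only"``.
    """
    if strands not in ("both", "plus_only"):
        raise ValueError(f"unknown strand mode {strands!r}")
    by_len = _pattern_map(kmer_set, strands)
    hits: List[GenomeHit] = []
    for chrom, raw in genome.items():
        seq = raw.upper()
        n = len(seq)
        for k, table in sorted(by_len.items()):
            lookup = table.get
            for i in range(n - k + 1):
                entries = lookup(seq[i:i + k])
                if entries:
                    for kmer_id, strand in entries:
                        hits.append(GenomeHit(chrom, i, i + k, strand, kmer_id))
    hits.sort()
    return hits


def count_occurrences(hits: Iterable[GenomeHit]) -> Counter:
    """Multiset count of hits per kmer_id."""
    return Counter(h.kmer_id for h in hits)


def hits_to_bed(hits: Iterable[GenomeHit]) -> pd.DataFrame:
    """Render hits as a BED6 frame (name=kmer_id, score=0)."""
    rows = [(h.chrom, h.start, h.end, h.kmer_id, 0, h.strand) for h in hits]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def hits_from_bed(frame: pd.DataFrame) -> List[GenomeHit]:
    return [GenomeHit(r.chrom, int(r.start), int(r.end), r.strand, r.name)
            for r in frame.itertuples(index=False)]
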