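"""Construction of the custom protein-binding-microarray probe universe.

The probe library has four kinds of members:

* ``alu_frequency`` — unique k-mers extracted from repeat consensus
  sequences, ranked by how often they occur in the genome, top N kept;
* ``alu_external_score`` / ``external_genomic`` — candidates ranked by an
  externally supplied score table (e.g. an SVM trained on earlier binding
  data; the scorer itself is out of scope, only its output table is read);
* ``dr1_perm`` / ``dr2_perm`` — systematic permutations of every window of
  ``w`` adjacent positions of a direct-repeat consensus (DR1: two AGGTCA
  half-sites with a 1-nt spacer; DR2: 2-nt spacer). A consensus of length L
  yields exactly (L - w + 1) * 4**w probes, the unmodified consensus
  included once per window and **not** deduplicated across windows;
* ``random_control_13`` / ``random_control_14`` — iid uniform k-mers used as
  negative controls, deduplicated against each other and against every
  non-control probe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .scan import count_occurrences, scan

_VALID = frozenset("ACGT")
_BASES = "ACGT"

DR1_CONSENSUS = "AGGTCAAAGGTCA"   # spacer written lowercase in the literature; plain A here
DR2_CONSENSUS = "AGGTCAAAAGGTCA"

PROBE_CATEGORIES = (
    "alu_frequency", "alu_external_score", "dr1_perm", "dr2_perm",
    "random_control_13", "random_control_14", "external_genomic",
)
CONTROL_CATEGORIES = ("random_control_13", "random_control_14")


@dataclass(frozen=True)
class Probe:
    id: str
    sequence: str
    category: str

    def __post_init__(self):
        if set(self.sequence) - _VALID:
            raise ValueError(f"probe {self.id!r} has non-ACGT sequence {self.sequence!r}")
        if self.category not in PROBE_CATEGORIES \
                and not self.category.startswith("random_control_"):
            raise ValueError(f"unknown probe category {self.category!r}")


@dataclass
class ProbeLibrary:
    """Ordered probe collection with construction provenance.

    ``raw_count`` counts every emitted probe; ``unique_sequence_count``
    counts distinct sequences across the whole library (permutation probes
    repeat the consensus, and categories can collide), so the two differ in
    general and both are reported.
    """

    probes: List[Probe]
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate probe ids in library")

    @property
    def raw_count(self) -> int:
        return len(self.probes)

    @property
    def unique_sequence_count(self) -> int:
        return len({p.sequence for p in self.probes})

    def category_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for p in self.probes:
            counts[p.category] = counts.get(p.category, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.id, p.category, p.sequence) for p in self.probes],
            columns=["id", "category", "sequence"],
        )


def extract_unique_kmers(consensus_set: Mapping[str, str], k: int) -> Set[str]:
    """Every distinct length-``k`` substring of the consensus sequences.

    Forward strand only (reverse complements are handled at genome-scan
    time). Windows containing any non-A/C/G/T character (N, ambiguity
    codes) are skipped. Sequences shorter than ``k`` contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not consensus_set:
        raise ValueError("empty consensus set")
    kmers: Set[str] = set()
    for seq in consensus_set.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            window = s[i:i + k]
            if not set(window) - _VALID:
                kmers.add(window)
    return kmers


def rank_kmers_by_genome_frequency(kmers: Iterable[str],
                                   genome: Mapping[str, str],
                                   strands: str = "both") -> List[Tuple[str, int]]:
    """k-mers with genome occurrence counts, most frequent first.

    Ties break lexicographically; k-mers absent from the genome appear with
    count 0.
    """
    kmers = sorted(set(kmers))
    counts = count_occurrences(scan(genome, kmers, strands=strands)) if kmers else {}
    return sorted(((k, counts.get(k, 0)) for k in kmers), key=lambda kv: (-kv[1], kv[0]))


def generate_window_permutation_probes(consensus: str, window: int,
                                       category: str = "dr1_perm",
                                       id_prefix: Optional[str] = None) -> List[Probe]:
    """All single-window substitution variants of a direct-repeat consensus.

    For each of the (L - window + 1) windows of ``window`` adjacent
    positions, emit all 4**window sequences obtained by replacing that
    window (the original consensus included), ordered by window start then
    by replacement in A<C<G<T lexicographic order. Variants are *not*
    deduplicated across windows: a 13-nt consensus with window 3 gives
    exactly 11 * 64 = 704 probes, a 14-nt consensus 12 * 64 = 768.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(consensus):
        raise ValueError("window longer than consensus")
    consensus = consensus.upper()
    if set(consensus) - _VALID:
        raise ValueError(f"consensus contains non-ACGT characters: {consensus!r}")
    prefix = id_prefix if id_prefix is not None else category
    probes = []
    for start in range(len(consensus) - window + 1):
        for combo in itertools.product(_BASES, repeat=window):
            variant = consensus[:start] + "".join(combo) + consensus[start + window:]
            probes.append(Probe(f"{prefix}_w{start:02d}_{''.join(combo)}", variant, category))
    return probes


def generate_random_controls(n: int, k: int, seed: int,
                             category: Optional[str] = None,
                             exclude: Iterable[str] = ()) -> List[Probe]:
    """``n`` distinct iid-uniform k-mers, avoiding the ``exclude`` sequences.

    Deterministic given ``seed``. Raises if ``n`` distinct sequences cannot
    be produced (pigeonhole on 4**k, or exhaustion of bounded retries).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if category is None:
        category = f"random_control_{k}"
    excluded = set(exclude)
    if 4 ** k < n + sum(1 for e in excluded if len(e) == k):
        raise ValueError(f"cannot draw {n} distinct {k}-mers: only {4 ** k} exist")
    rng = np.random.default_rng(seed)
    chosen: List[str] = []
    seen = set(excluded)
    max_tries = 1000 * n
    tries = 0
    while len(chosen) < n:
        if tries >= max_tries:
            raise RuntimeError(f"could not draw {n} distinct {k}-mers after {max_tries} tries")
        tries += 1
        seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=k))
        if seq not in seen:
            seen.add(seq)
            chosen.append(seq)
    return [Probe(f"{category}_{i:04d}", seq, category) for i, seq in enumerate(chosen)]


@dataclass
class LibraryParams:
    """Construction parameters of the probe library.

    Defaults reproduce the published array composition: top 100
    genome-frequency k-mers, top 100 externally scored k-mers, window-3
    permutations of the DR1/DR2 consensus, 100 13-mer and 50 14-mer random
    controls.
    """

    k: int = 13
    top_n_frequency: int = 100
    top_n_external: int = 100
    dr1_consensus: str = DR1_CONSENSUS
    dr2_consensus: str = DR2_CONSENSUS
    permutation_window: int = 3
    n_controls_13: int = 100
    n_controls_14: int = 50
    control_seed: int = 0
    strands: str = "both"


def assemble_library(consensus_set: Mapping[str, str],
                     genome: Mapping[str, str],
                     external_scores: Optional[Mapping[str, float] | pd.DataFrame] = None,
                     params: Optional[LibraryParams] = None) -> ProbeLibrary:
    """Build the full probe library from a consensus set and a genome.

    Sequence-level deduplication is applied only between the two
    consensus-derived categories (``alu_frequency`` and
    ``alu_external_score``), whose union is described as unique; the
    external-score list keeps only k-mers not already selected by
    frequency. Permutation probes keep their full printed per-category
    counts even though sequences repeat. ``external_genomic`` candidates
    (arbitrary externally scored sequences not from the consensus set) are
    included as given, deduplicated within the category.
    """
    params = params or LibraryParams()
    kmers = extract_unique_kmers(consensus_set, params.k)
    ranked = rank_kmers_by_genome_frequency(kmers, genome, strands=params.strands)
    top_frequency = [kmer for kmer, _ in ranked[:params.top_n_frequency]]

    probes: List[Probe] = [
        Probe(f"alu_frequency_{i:04d}", seq, "alu_frequency")
        for i, seq in enumerate(top_frequency)
    ]

    scores: Dict[str, float] = {}
    if external_scores is not None:
        if isinstance(external_scores, pd.DataFrame):
            scores = dict(zip(external_scores["sequence"], external_scores["score"]))
        else:
            scores = dict(external_scores)

    if scores:
        chosen = set(top_frequency)
        scored_kmers = sorted((s for s in kmers if s in scores and s not in chosen),
                              key=lambda s: (-scores[s], s))[:params.top_n_external]
        probes += [Probe(f"alu_external_score_{i:04d}", seq, "alu_external_score")
                   for i, seq in enumerate(scored_kmers)]
        genomic = sorted((s for s in scores if s not in kmers), key=lambda s: (-scores[s], s))
        seen_genomic: Set[str] = set()
        for i, seq in enumerate(genomic):
            if seq not in seen_genomic:
                seen_genomic.add(seq)
                probes.append(Probe(f"external_genomic_{i:04d}", seq, "external_genomic"))

    probes += generate_window_permutation_probes(
        params.dr1_consensus, params.permutation_window, category="dr1_perm")
    probes += generate_window_permutation_probes(
        params.dr2_consensus, params.permutation_window, category="dr2_perm")

    non_control = {p.sequence for p in probes}
    probes += generate_random_controls(params.n_controls_13, 13, params.control_seed,
                                       category="random_control_13", exclude=non_control)
    non_control = {p.sequence for p in probes}
    probes += generate_random_controls(params.n_controls_14, 14, params.control_seed + 1,
                                       category="random_control_14", exclude=non_control)

    library = ProbeLibrary(probes)
    library.provenance = {
        "params": params,
        "n_consensus_kmers": len(kmers),
        "raw_count": library.raw_count,
        "unique_sequence_count": library.unique_sequence_count,
        "category_counts": library.category_counts(),
    }
    return library
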