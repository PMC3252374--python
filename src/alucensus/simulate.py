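"""Synthetic genomes, repeat annotations and PBM score tables.

The generator emulates the statistical structure the census assumes,
so every downstream module is testable without any external download:

* a small library of ~300-nt "Alu-like" consensus sequences, iid over
  A/C/G/T at a configurable GC content, named by a synthetic subfamily
  scheme (AluY_syn1, AluS_syn1, AluJ_syn1, ...) whose prefixes map onto
  the young/intermediate/old family classes;
* a genome consisting of an iid background with planted, point-mutated,
  optionally 5'-truncated copies of each consensus, on both strands,
  never overlapping, with RepeatMasker-style 1-based consensus offsets
  recorded as ground truth;
* per-family substitution rates (young families diverge less), the knob
  that reproduces the young > old ordering of percent-of-elements-with-site;
* PBM score tables in which designated binder probes are shifted above a
  normal control null (defaults put the control mean + 2 SD threshold at
  0.612, inside the score scale of the reference array).

All randomness flows from one integer seed through deterministic
per-component substreams, so a fixed config reproduces byte-identical
fixture bundles.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import io as axio
from .probes import Probe, CONTROL_CATEGORIES
from .repeats import RepeatFeature, features_to_bed, write_repeatmasker_out
from .scan import reverse_complement

_BASES = "ACGT"
# synthetic subfamily labels are chosen so the prefix rules of
# classify_family map them onto the AluY / AluS / AluJ family classes
_FAMILY_LABELS = ("AluY_syn", "AluS_syn", "AluJ_syn")
# young / intermediate / old divergence ladder, per consensus in order
_DEFAULT_RATES = (0.02, 0.10, 0.25)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic fixture.

    ``substitution_rate`` may be a single per-base probability or one per
    consensus; the default three-family ladder (0.02 / 0.10 / 0.25) mimics
    the divergence ordering of young, intermediate and old repeat
    families. PBM score defaults place the binder threshold
    (control mean + 2 SD) at 0.452 + 2 * 0.08 = 0.612.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_content: float = 0.41
    n_consensus: int = 3
    consensus_length: int = 300
    n_copies_per_consensus: int = 50
    substitution_rate: Union[float, Tuple[float, ...]] = _DEFAULT_RATES
    truncation_prob: float = 0.1
    min_copy_fraction: float = 0.5
    n_genes: int = 20
    n_accessible_regions: int = 10
    n_binder_probes: int = 33
    pbm_binder_mean: float = 0.75
    pbm_control_mean: float = 0.452
    pbm_sd: float = 0.08

    def rates(self) -> Tuple[float, ...]:
        """Per-consensus substitution rates, broadcast from a scalar."""
        raw = self.substitution_rate
        if isinstance(raw, (int, float)):
            rates = (float(raw),) * self.n_consensus
        else:
            rates = tuple(float(r) for r in raw)
            if len(rates) == 1:
                rates = rates * self.n_consensus
            if len(rates) < self.n_consensus:
                # cycle the ladder over additional consensus sequences
                rates = tuple(rates[i % len(rates)] for i in range(self.n_consensus))
            rates = rates[: self.n_consensus]
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("substitution rates must lie in [0, 1)")
        return rates

    def validate(self) -> None:
        if self.n_consensus < 1:
            raise ValueError("n_consensus must be >= 1")
        if self.consensus_length < 13:
            raise ValueError("consensus_length must be >= 13")
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if not (0.0 <= self.truncation_prob <= 1.0):
            raise ValueError("truncation_prob must be in [0, 1]")
        if not (0.0 < self.min_copy_fraction <= 1.0):
            raise ValueError("min_copy_fraction must be in (0, 1]")
        self.rates()


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted repeat copy.

    Genomic coordinates are 0-based half-open; consensus coordinates are
    1-based inclusive, so end - start == consensus_end - consensus_begin + 1.
    """

    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    consensus_begin: int
    consensus_end: int

    def __post_init__(self):
        if self.end - self.start != self.consensus_end - self.consensus_begin + 1:
            raise ValueError("planted interval length disagrees with consensus offsets")


def _component_rng(cfg: SimulationConfig, component: int) -> np.random.Generator:
    """Deterministic substream: one global seed, one index per component."""
    return np.random.default_rng([int(cfg.seed), component])


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


def simulate_consensus_set(cfg: SimulationConfig) -> Dict[str, str]:
    """Named consensus sequences, iid at the configured GC content.

    Names cycle through the synthetic family labels: with three consensus
    sequences the set is AluY_syn1, AluS_syn1, AluJ_syn1.
    """
    cfg.validate()
    rng = _component_rng(cfg, 1)
    out: Dict[str, str] = {}
    for i in range(cfg.n_consensus):
        label = _FAMILY_LABELS[i % len(_FAMILY_LABELS)]
        name = f"{label}{i // len(_FAMILY_LABELS) + 1}"
        out[name] = _random_sequence(rng, cfg.consensus_length, cfg.gc_content)
    return out


def random_background(cfg: SimulationConfig) -> str:
    """The iid background genome sequence (before planting)."""
    cfg.validate()
    return _random_sequence(_component_rng(cfg, 2), cfg.genome_length, cfg.gc_content)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    mask = rng.random(len(chars)) < rate
    for pos in np.flatnonzero(mask):
        alternatives = [b for b in _BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def plant_copies(genome_background: str,
                 consensus_set: Mapping[str, str],
                 cfg: SimulationConfig,
                 chrom: str = "chrS1",
                 ) -> Tuple[str, List[PlantRecord], List[RepeatFeature]]:
    """Plant mutated copies of each consensus into the background.

    Each copy is the consensus (reverse-complemented on the minus strand)
    with iid substitutions at that consensus's rate, optionally 5'-truncated
    (consensus_begin moves right, consensus_end stays at the consensus
    length, at least ``min_copy_fraction`` retained). Copies are shuffled
    and separated by multinomially distributed background gaps, so they
    never overlap; the annotation rows agree with the plants exactly.
    """
    cfg.validate()
    rng = _component_rng(cfg, 3)
    rates = cfg.rates()
    L = cfg.consensus_length
    names = list(consensus_set)

    copies: List[Tuple[str, str, int, int, str]] = []  # (subfamily, strand, begin, end, seq)
    for idx, name in enumerate(names):
        consensus = consensus_set[name]
        rate = rates[idx % len(rates)]
        for _ in range(cfg.n_copies_per_consensus):
            begin = 1
            if cfg.truncation_prob > 0 and rng.random() < cfg.truncation_prob:
                min_len = int(np.ceil(len(consensus) * cfg.min_copy_fraction))
                begin = 1 + int(rng.integers(0, len(consensus) - min_len + 1))
            segment = consensus[begin - 1:]
            segment = _mutate(rng, segment, rate)
            strand = "+" if rng.random() < 0.5 else "-"
            genomic = segment if strand == "+" else reverse_complement(segment)
            copies.append((name, strand, begin, len(consensus), genomic))

    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]
    total = sum(len(c[4]) for c in copies)
    slack = len(genome_background) - total
    if slack < 0:
        raise ValueError(f"genome of {len(genome_background)} bases cannot hold "
                         f"{total} planted bases")
    gaps = rng.multinomial(slack, [1.0 / (len(copies) + 1)] * (len(copies) + 1))

    pieces: List[str] = []
    plants: List[PlantRecord] = []
    features: List[RepeatFeature] = []
    cursor = 0
    bg_cursor = 0
    for gap, (name, strand, begin, end, genomic) in zip(gaps, copies):
        pieces.append(genome_background[bg_cursor:bg_cursor + gap])
        bg_cursor += gap
        cursor += gap
        pieces.append(genomic)
        plants.append(PlantRecord(chrom, cursor, cursor + len(genomic), strand,
                                  name, begin, end))
        features.append(RepeatFeature(chrom, cursor, cursor + len(genomic), strand,
                                      name, begin, end))
        cursor += len(genomic)
    pieces.append(genome_background[bg_cursor:bg_cursor + gaps[-1]])
    genome = "".join(pieces)
    plants.sort(key=lambda p: p.start)
    features.sort(key=lambda f: f.start)
    return genome, plants, features


def simulate_pbm_scores(probes: Sequence[Probe],
                        cfg: SimulationConfig,
                        binder_ids: Iterable[str] = (),
                        n_grids: int = 4,
                        n_spots: int = 4) -> pd.DataFrame:
    """Replicate spot scores: normal noise around a binder or control mean.

    Probes in ``binder_ids`` draw all spots from
    Normal(pbm_binder_mean, pbm_sd); every other probe, controls included,
    draws from Normal(pbm_control_mean, pbm_sd). The table has one row per
    probe and one ``score_g{g}_r{r}`` column per spot of each grid.
    """
    cfg.validate()
    if not any(p.category in CONTROL_CATEGORIES for p in probes):
        raise ValueError("probe set has no random_control category")
    binder_ids = set(binder_ids)
    rng = _component_rng(cfg, 4)
    columns = [f"score_g{g + 1}_r{r + 1}" for g in range(n_grids) for r in range(n_spots)]
    rows = []
    for probe in probes:
        mu = cfg.pbm_binder_mean if probe.id in binder_ids else cfg.pbm_control_mean
        draws = rng.normal(mu, cfg.pbm_sd, size=n_grids * n_spots) if cfg.pbm_sd > 0 \
            else np.full(n_grids * n_spots, mu)
        rows.append([probe.id, probe.category, probe.sequence, *np.round(draws, 6)])
    return pd.DataFrame(rows, columns=["id", "category", "sequence", *columns])


def plants_to_frame(plants: Sequence[PlantRecord]) -> pd.DataFrame:
    rows = [(p.chrom, p.start, p.end, p.strand, p.subfamily,
             p.consensus_begin, p.consensus_end) for p in plants]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "subfamily",
                                       "consensus_begin", "consensus_end"])


def plants_from_frame(frame: pd.DataFrame) -> List[PlantRecord]:
    return [PlantRecord(r.chrom, int(r.start), int(r.end), r.strand, r.subfamily,
                        int(r.consensus_begin), int(r.consensus_end))
            for r in frame.itertuples(index=False)]


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | os.PathLike,
                         ) -> Dict[str, Path]:
    """Generate and write the complete plain-text fixture bundle.

    Emits genome FASTA, consensus FASTA, RepeatMasker-style ``.out`` plus
    BED6 annotation, TSS BED, accessible-region (DNase-like) BED, a PBM
    score TSV over the consensus-derived probes plus random controls, and
    the ground-truth plants TSV. Deterministic: same config, same bytes.
    """
    from .probes import (LibraryParams, extract_unique_kmers,
                         generate_random_controls, rank_kmers_by_genome_frequency)

    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    consensus = simulate_consensus_set(cfg)
    background = random_background(cfg)
    genome, plants, features = plant_copies(background, consensus, cfg)
    genome_map = {"chrS1": genome}

    # TSS and accessible regions over the planted genome
    rng = _component_rng(cfg, 5)
    tss_rows = []
    for i in range(cfg.n_genes):
        pos = int(rng.integers(0, cfg.genome_length))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_rows.append(("chrS1", pos, pos + 1, f"gene{i + 1:04d}", 0, strand))
    tss = pd.DataFrame(tss_rows, columns=axio.BED6_COLUMNS)

    region_rows = []
    for i in range(cfg.n_accessible_regions):
        start = int(rng.integers(0, max(1, cfg.genome_length - 500)))
        region_rows.append(("chrS1", start, start + 500, f"acc{i + 1:04d}", 0, "."))
    accessible = pd.DataFrame(region_rows, columns=axio.BED6_COLUMNS)

    # PBM probes: per-family top consensus k-mers by genome frequency plus
    # random controls. Selection is stratified over the consensus set so
    # every synthetic family contributes probes and designated binders
    # (the youngest family would otherwise monopolize a global top-N,
    # since its copies are the least diverged).
    params = LibraryParams()
    probe_quota = max(1, params.top_n_frequency // len(consensus))
    binder_quota = max(1, cfg.n_binder_probes // len(consensus))
    probes: List[Probe] = []
    binder_ids: List[str] = []
    seen: set = set()
    for name, seq in consensus.items():
        ranked = rank_kmers_by_genome_frequency(
            extract_unique_kmers({name: seq}, 13), genome_map)
        picked = [k for k, _ in ranked[:probe_quota] if k not in seen]
        seen.update(picked)
        start = len(probes)
        probes += [Probe(f"alu_frequency_{start + j:04d}", kmer, "alu_frequency")
                   for j, kmer in enumerate(picked)]
        binder_ids += [p.id for p in probes[start:start + binder_quota]]
    probes += generate_random_controls(params.n_controls_13, 13, params.control_seed,
                                       category="random_control_13",
                                       exclude={p.sequence for p in probes})
    scores = simulate_pbm_scores(probes, cfg, binder_ids=binder_ids)

    paths = {
        "genome": outdir / "genome.fa",
        "consensus": outdir / "consensus.fa",
        "repeats_out": outdir / "repeats.out",
        "repeats_bed": outdir / "repeats.bed",
        "tss": outdir / "tss.bed",
        "accessible": outdir / "dnase.bed",
        "pbm": outdir / "pbm_scores.tsv",
        "plants": outdir / "plants.tsv",
    }
    axio.write_fasta(genome_map, paths["genome"])
    axio.write_fasta(consensus, paths["consensus"])
    write_repeatmasker_out(features, paths["repeats_out"])
    axio.write_bed6(features_to_bed(features), paths["repeats_bed"])
    axio.write_bed6(tss, paths["tss"])
    axio.write_bed6(accessible, paths["accessible"])
    axio.write_tsv(scores, paths["pbm"])
    axio.write_tsv(plants_to_frame(plants), paths["plants"])
    return paths
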