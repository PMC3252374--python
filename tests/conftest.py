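"""Shared fixtures: small in-memory synthetic genomes and a naive scanner oracle."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List

import pytest

from alucensus.repeats import RepeatFeature
from alucensus.scan import reverse_complement
from alucensus.simulate import (PlantRecord, SimulationConfig, plant_copies,
                                random_background, simulate_consensus_set)


def naive_scan(genome: Dict[str, str], kmers, strands: str = "both") -> Counter:
    """Brute-force O(n*m) sliding-window oracle, independent of the scanner.

    Returns a multiset of (chrom, start, end, strand, kmer_id) tuples.
    Compares substrings pattern by pattern; in ``both`` mode a locus is
    also compared against the pattern's reverse complement, except for
    palindromes which only yield the canonical plus-strand hit.
    """
    hits: Counter = Counter()
    for chrom, raw in genome.items():
        seq = raw.upper()
        for kmer in kmers:
            k = len(kmer)
            rc = reverse_complement(kmer)
            for i in range(len(seq) - k + 1):
                window = seq[i:i + k]
                if window == kmer:
                    hits[(chrom, i, i + k, "+", kmer)] += 1
                elif strands == "both" and rc != kmer and window == rc:
                    hits[(chrom, i, i + k, "-", kmer)] += 1
    return hits


@dataclass
class Bundle:
    cfg: SimulationConfig
    consensus: Dict[str, str]
    genome: Dict[str, str]
    plants: List[PlantRecord]
    features: List[RepeatFeature]


def make_bundle(**overrides) -> Bundle:
    cfg = SimulationConfig(**overrides)
    consensus = simulate_consensus_set(cfg)
    background = random_background(cfg)
    genome, plants, features = plant_copies(background, consensus, cfg)
    return Bundle(cfg, consensus, {"chrS1": genome}, plants, features)


@pytest.fixture(scope="session")
def zero_divergence_bundle() -> Bundle:
    """One family, ten exact full-length copies: ground truth is transparent."""
    return make_bundle(seed=11, n_consensus=1, n_copies_per_consensus=10,
                       substitution_rate=0.0, truncation_prob=0.0,
                       genome_length=40_000, n_genes=5, n_accessible_regions=3)
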