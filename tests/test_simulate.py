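"""Synthetic-data generator: determinism, composition, planting, PBM noise."""

import math

import numpy as np
import pandas as pd
import pytest

from alucensus import io as axio
from alucensus.probes import Probe
from alucensus.repeats import parse_repeatmasker_out
from alucensus.scan import reverse_complement
from alucensus.simulate import (SimulationConfig, plants_from_frame,
                                simulate_consensus_set, simulate_pbm_scores,
                                write_fixture_bundle)

from conftest import make_bundle


class TestConsensusSet:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=1, n_consensus=2, consensus_length=50)
        first = simulate_consensus_set(cfg)
        second = simulate_consensus_set(cfg)
        assert first == second
        assert all(len(s) == 50 for s in first.values())
        assert len(first) == 2

    def test_different_seeds_differ(self):
        a = simulate_consensus_set(SimulationConfig(seed=1))
        b = simulate_consensus_set(SimulationConfig(seed=2))
        assert a != b

    def test_gc_one_gives_only_gc(self):
        cfg = SimulationConfig(seed=3, gc_content=1.0, n_consensus=1)
        (seq,) = simulate_consensus_set(cfg).values()
        assert set(seq) <= {"G", "C"}

    def test_gc_fraction_within_binomial_bound(self):
        # 3-SD binomial band: sd = sqrt(0.5*0.5/10000) = 0.005
        cfg = SimulationConfig(seed=4, gc_content=0.5, n_consensus=1,
                               consensus_length=10_000)
        (seq,) = simulate_consensus_set(cfg).values()
        gc = sum(base in "GC" for base in seq) / len(seq)
        assert abs(gc - 0.5) <= 3 * math.sqrt(0.25 / 10_000)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_consensus_set(SimulationConfig(consensus_length=5))
        with pytest.raises(ValueError):
            simulate_consensus_set(SimulationConfig(n_consensus=0))
        with pytest.raises(ValueError):
            simulate_consensus_set(SimulationConfig(substitution_rate=1.0))

    def test_family_labels_cycle(self):
        names = list(simulate_consensus_set(SimulationConfig(seed=1, n_consensus=4)))
        assert names == ["AluY_syn1", "AluS_syn1", "AluJ_syn1", "AluY_syn2"]


class TestPlantCopies:
    def test_zero_substitution_copies_are_exact(self, zero_divergence_bundle):
        bundle = zero_divergence_bundle
        (consensus,) = bundle.consensus.values()
        genome = bundle.genome["chrS1"]
        for plant in bundle.plants:
            segment = consensus[plant.consensus_begin - 1:plant.consensus_end]
            observed = genome[plant.start:plant.end]
            expected = segment if plant.strand == "+" else reverse_complement(segment)
            assert observed == expected

    def test_no_truncation_means_full_length(self, zero_divergence_bundle):
        for plant in zero_divergence_bundle.plants:
            assert plant.consensus_begin == 1
            assert plant.consensus_end == zero_divergence_bundle.cfg.consensus_length

    def test_mean_mismatch_count_matches_binomial(self):
        # 100 copies of a 300-nt consensus at rate 0.1: per-copy mismatches
        # ~ Binomial(300, 0.1); the mean over copies has SD sqrt(27/100).
        bundle = make_bundle(seed=7, n_consensus=1, n_copies_per_consensus=100,
                             substitution_rate=0.1, truncation_prob=0.0,
                             genome_length=80_000)
        (consensus,) = bundle.consensus.values()
        genome = bundle.genome["chrS1"]
        mismatches = []
        for plant in bundle.plants:
            observed = genome[plant.start:plant.end]
            if plant.strand == "-":
                observed = reverse_complement(observed)
            mismatches.append(sum(a != b for a, b in zip(observed, consensus)))
        expected = 300 * 0.1
        band = 3 * math.sqrt(300 * 0.1 * 0.9 / 100)
        assert abs(np.mean(mismatches) - expected) <= band

    def test_plants_and_annotation_agree_and_do_not_overlap(self):
        bundle = make_bundle(seed=9, genome_length=120_000, n_copies_per_consensus=30)
        assert len(bundle.plants) == len(bundle.features)
        for plant, feature in zip(bundle.plants, bundle.features):
            assert (plant.chrom, plant.start, plant.end, plant.strand,
                    plant.subfamily, plant.consensus_begin, plant.consensus_end) == \
                   (feature.chrom, feature.start, feature.end, feature.strand,
                    feature.subfamily, feature.consensus_begin, feature.consensus_end)
        intervals = sorted((p.start, p.end) for p in bundle.plants)
        assert all(prev_end <= start for (_, prev_end), (start, _)
                   in zip(intervals, intervals[1:]))

    def test_conservation_of_planted_bases(self):
        bundle = make_bundle(seed=9, genome_length=120_000, n_copies_per_consensus=30)
        planted = sum(p.end - p.start for p in bundle.plants)
        annotated = sum(f.end - f.start for f in bundle.features)
        assert planted == annotated
        assert len(bundle.genome["chrS1"]) == bundle.cfg.genome_length

    def test_truncation_respects_min_fraction(self):
        bundle = make_bundle(seed=13, n_consensus=1, n_copies_per_consensus=80,
                             substitution_rate=0.0, truncation_prob=1.0,
                             min_copy_fraction=0.5, genome_length=80_000)
        L = bundle.cfg.consensus_length
        lengths = [p.end - p.start for p in bundle.plants]
        assert all(L * 0.5 <= n <= L for n in lengths)
        assert any(n < L for n in lengths)  # truncation actually happens
        assert all(p.consensus_end == L for p in bundle.plants)

    def test_genome_capacity_overflow_raises(self):
        with pytest.raises(ValueError, match="cannot hold"):
            make_bundle(seed=1, genome_length=1000, n_copies_per_consensus=10)


class TestPbmScores:
    def _probes(self):
        return [Probe("p1", "ACGTACGTACGTA", "alu_frequency"),
                Probe("p2", "TTTTACGTACGTA", "alu_frequency"),
                Probe("c1", "GGGGACGTACGTA", "random_control_13"),
                Probe("c2", "CCCCACGTACGTA", "random_control_13")]

    def test_requires_control_category(self):
        cfg = SimulationConfig(seed=1)
        with pytest.raises(ValueError, match="random_control"):
            simulate_pbm_scores(self._probes()[:2], cfg)

    def test_zero_sd_gives_identical_replicates(self):
        cfg = SimulationConfig(seed=1, pbm_sd=0.0)
        table = simulate_pbm_scores(self._probes(), cfg, binder_ids=["p1"])
        score_cols = [c for c in table.columns if c.startswith("score")]
        assert len(score_cols) == 16
        for _, row in table.iterrows():
            assert row[score_cols].nunique() == 1
        binder_row = table.loc[table["id"] == "p1", score_cols].iloc[0]
        control_row = table.loc[table["id"] == "c1", score_cols].iloc[0]
        assert binder_row.iloc[0] == cfg.pbm_binder_mean
        assert control_row.iloc[0] == cfg.pbm_control_mean

    def test_fixed_seed_reproduces_table(self):
        cfg = SimulationConfig(seed=5)
        a = simulate_pbm_scores(self._probes(), cfg, binder_ids=["p1"])
        b = simulate_pbm_scores(self._probes(), cfg, binder_ids=["p1"])
        pd.testing.assert_frame_equal(a, b)


class TestFixtureBundle:
    def test_bundle_round_trips_through_own_readers(self, tmp_path):
        cfg = SimulationConfig(seed=2, genome_length=60_000,
                               n_copies_per_consensus=15, n_genes=4,
                               n_accessible_regions=2)
        paths = write_fixture_bundle(cfg, tmp_path / "bundle")
        genome = axio.read_fasta(paths["genome"])
        assert len(genome["chrS1"]) == cfg.genome_length
        consensus = axio.read_fasta(paths["consensus"])
        assert len(consensus) == cfg.n_consensus
        features = parse_repeatmasker_out(paths["repeats_out"])
        plants = plants_from_frame(axio.read_tsv(paths["plants"]))
        assert len(features) == len(plants) == 45
        for f, p in zip(features, plants):
            assert (f.start, f.end, f.strand, f.subfamily,
                    f.consensus_begin, f.consensus_end) == \
                   (p.start, p.end, p.strand, p.subfamily,
                    p.consensus_begin, p.consensus_end)
        assert len(axio.read_bed6(paths["tss"])) == 4
        assert len(axio.read_bed6(paths["accessible"])) == 2
        scores = axio.read_tsv(paths["pbm"])
        assert {"id", "category", "sequence"} <= set(scores.columns)
        assert scores["category"].str.startswith("random_control").any()

    def test_no_genes_yields_empty_valid_tss(self, tmp_path):
        cfg = SimulationConfig(seed=2, genome_length=60_000,
                               n_copies_per_consensus=15, n_genes=0)
        paths = write_fixture_bundle(cfg, tmp_path / "bundle")
        tss = axio.read_bed6(paths["tss"])
        assert len(tss) == 0

    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = SimulationConfig(seed=3, genome_length=50_000,
                               n_copies_per_consensus=12)
        paths_a = write_fixture_bundle(cfg, tmp_path / "a")
        paths_b = write_fixture_bundle(cfg, tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key
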