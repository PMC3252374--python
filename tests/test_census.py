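"""Census tables: percent arithmetic, multiplicity, family summaries, histograms."""

import numpy as np
import pytest

from alucensus.census import (family_summary, kmer_frequency_table,
                              multiplicity_distribution, percent_half_up,
                              position_histogram)
from alucensus.repeats import RepeatFeature, assign_hits
from alucensus.scan import GenomeHit


def annotate(hit_specs, repeats):
    """hit_specs: (chrom, start, kmer) with k = len(kmer)."""
    hits = [GenomeHit(chrom, start, start + len(kmer), "+", kmer)
            for chrom, start, kmer in hit_specs]
    return assign_hits(hits, repeats)


class TestPercentHalfUp:
    def test_matches_printed_two_decimal_cells(self):
        assert percent_half_up(469851, 471728) == 99.60
        assert percent_half_up(128437, 140510) == 91.41
        assert percent_half_up(3776, 3851) == 98.05

    def test_half_up_at_boundary(self):
        assert percent_half_up(1, 800) == 0.13          # 0.125 rounds up
        assert percent_half_up(125, 100000) == 0.13
        assert percent_half_up(1, 3) == 33.33

    def test_zero_denominator_guarded(self):
        assert percent_half_up(0, 0) is None

    def test_one_decimal(self):
        assert percent_half_up(1252918, 1320513, ndigits=1) == 94.9


ALU = RepeatFeature("chr1", 100, 400, "+", "AluY_syn1", 1, 300)
ALU2 = RepeatFeature("chr1", 600, 900, "+", "AluS_syn1", 1, 300)
OTHER = RepeatFeature("chr1", 1200, 1500, "+", "Tigger2a", 1, 300)


class TestKmerFrequencyTable:
    def test_all_hits_inside_alus_give_100_percent(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA"),
                              ("chr1", 130, "AAAAAAAAAAAAA"),
                              ("chr1", 610, "CCCCCCCCCCCCC")], [ALU, ALU2])
        table = kmer_frequency_table(annotated)
        assert list(table["percent"]) == [100.0, 100.0]
        assert table.set_index("sequence").loc["AAAAAAAAAAAAA", "n_in_genome"] == 2

    def test_non_alu_and_outside_hits_lower_percent(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA"),
                              ("chr1", 1210, "AAAAAAAAAAAAA"),
                              ("chr1", 2000, "AAAAAAAAAAAAA"),
                              ("chr1", 3000, "AAAAAAAAAAAAA")],
                             [ALU, OTHER])
        table = kmer_frequency_table(annotated)
        row = table.iloc[0]
        assert row["n_in_class"] == 1          # only the AluY-contained hit
        assert row["n_in_genome"] == 4
        assert row["percent"] == 25.0

    def test_zero_genome_count_gives_empty_percent(self):
        table = kmer_frequency_table([], kmers=["AAAAAAAAAAAAA"])
        assert table.loc[0, "n_in_genome"] == 0
        assert np.isnan(table.loc[0, "percent"])

    def test_sorted_by_percent_then_count(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA"),
                              ("chr1", 130, "CCCCCCCCCCCCC"),
                              ("chr1", 2000, "CCCCCCCCCCCCC")], [ALU])
        table = kmer_frequency_table(annotated)
        assert list(table["sequence"]) == ["AAAAAAAAAAAAA", "CCCCCCCCCCCCC"]

    def test_pbm_scores_attached(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA")], [ALU])
        table = kmer_frequency_table(annotated,
                                     pbm_scores={"AAAAAAAAAAAAA": 0.84})
        assert table.loc[0, "pbm_score"] == 0.84


class TestMultiplicityDistribution:
    def test_constructed_two_sites_in_each_of_five_copies(self):
        repeats = [RepeatFeature("chr1", i * 1000, i * 1000 + 300, "+",
                                 "AluY_syn1", 1, 300) for i in range(5)]
        specs = []
        for i in range(5):
            specs.append(("chr1", i * 1000 + 20, "AAAAAAAAAAAAA"))
            specs.append(("chr1", i * 1000 + 60, "CCCCCCCCCCCCC"))
        frame, totals = multiplicity_distribution(annotate(specs, repeats))
        assert frame.to_dict("records") == [
            {"sites_per_element": 2, "n_elements": 5, "n_sites": 10}]
        assert totals == (5, 10)

    def test_repeat_occurrences_of_same_kmer_count_separately(self):
        specs = [("chr1", 110, "AAAAAAAAAAAAA"), ("chr1", 150, "AAAAAAAAAAAAA")]
        frame, totals = multiplicity_distribution(annotate(specs, [ALU]))
        assert totals == (1, 2)

    def test_empty_hits_give_empty_table(self):
        frame, totals = multiplicity_distribution([])
        assert len(frame) == 0
        assert totals == (0, 0)

    def test_row_identity_and_totals_consistency(self):
        rng = np.random.default_rng(0)
        repeats = [RepeatFeature("chr1", i * 1000, i * 1000 + 300, "+",
                                 "AluY_syn1", 1, 300) for i in range(20)]
        specs = []
        for i in range(20):
            for j in range(int(rng.integers(0, 5))):
                specs.append(("chr1", i * 1000 + 10 + j * 20, "AAAAAAAAAAAAA"))
        frame, (n_elements, n_sites) = multiplicity_distribution(
            annotate(specs, repeats))
        assert (frame["n_sites"] ==
                frame["sites_per_element"] * frame["n_elements"]).all()
        assert n_elements == frame["n_elements"].sum()
        assert n_sites == len(specs)


class TestFamilySummary:
    repeats = [ALU, ALU2, OTHER,
               RepeatFeature("chr1", 1700, 2000, "+", "AluY_syn2", 1, 300)]

    def test_family_level_counts_and_percent(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA"),
                              ("chr1", 1210, "CCCCCCCCCCCCC")], self.repeats)
        table = family_summary(annotated, self.repeats, level="family")
        by_name = table.set_index("family_or_subfamily")
        assert by_name.loc["AluY", "n_with_site"] == 1
        assert by_name.loc["AluY", "n_total"] == 2
        assert by_name.loc["AluY", "percent"] == 50.0
        assert by_name.loc["AluS", "n_with_site"] == 0
        assert by_name.loc["AluS", "percent"] == 0.0
        assert by_name.loc["other_named", "n_with_site"] == 1

    def test_subfamily_level(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA")], self.repeats)
        table = family_summary(annotated, self.repeats, level="subfamily")
        by_name = table.set_index("family_or_subfamily")
        assert by_name.loc["AluY_syn1", "n_with_site"] == 1
        assert by_name.loc["AluY_syn2", "n_with_site"] == 0

    def test_alu_family_counts_sum_to_alu_total(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA"),
                              ("chr1", 610, "AAAAAAAAAAAAA"),
                              ("chr1", 1750, "AAAAAAAAAAAAA")], self.repeats)
        family = family_summary(annotated, self.repeats, level="family")
        alu_rows = family[family["family_or_subfamily"] != "other_named"]
        _, (n_elements, _) = multiplicity_distribution(annotated)
        assert alu_rows["n_with_site"].sum() == n_elements

    def test_percent_cells_self_consistent(self):
        annotated = annotate([("chr1", 110, "AAAAAAAAAAAAA")], self.repeats)
        table = family_summary(annotated, self.repeats, level="family")
        for _, row in table.iterrows():
            assert row["percent"] == percent_half_up(row["n_with_site"],
                                                     row["n_total"])

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            family_summary([], [], level="superfamily")


class TestPositionHistogram:
    def test_single_planted_offset_gives_single_peak(self):
        repeats = [RepeatFeature("chr1", i * 1000, i * 1000 + 300, "+",
                                 "AluY_syn1", 1, 300) for i in range(7)]
        specs = [("chr1", i * 1000 + 30, "AAAAAAAAAAAAA") for i in range(7)]
        hist = position_histogram(annotate(specs, repeats), family_class="AluY")
        assert hist.to_dict() == {31: 7}

    def test_two_subfamilies_mixed_offsets_bimodal(self):
        repeats = []
        specs = []
        for i in range(4):
            repeats.append(RepeatFeature("chr1", i * 1000, i * 1000 + 300, "+",
                                         "AluY_syn1", 1, 300))
            specs.append(("chr1", i * 1000 + 30, "AAAAAAAAAAAAA"))
        for i in range(4, 9):
            repeats.append(RepeatFeature("chr1", i * 1000, i * 1000 + 300, "+",
                                         "AluS_syn1", 1, 300))
            specs.append(("chr1", i * 1000 + 61, "CCCCCCCCCCCCC"))
        annotated = annotate(specs, repeats)
        assert position_histogram(annotated).to_dict() == {31: 4, 62: 5}
        assert position_histogram(annotated, subfamily="AluS_syn1").to_dict() == {62: 5}

    def test_minus_strand_positions_are_consensus_relative(self):
        repeat = RepeatFeature("chr1", 100, 400, "-", "AluY_syn1", 1, 300)
        # hit ending at the repeat's genomic end is consensus position 1
        annotated = annotate([("chr1", 387, "AAAAAAAAAAAAA")], [repeat])
        assert position_histogram(annotated).to_dict() == {1: 1}

    def test_empty_hits_empty_histogram(self):
        assert len(position_histogram([])) == 0

    def test_bin_width_groups_positions(self):
        repeats = [RepeatFeature("chr1", 0, 300, "+", "AluY_syn1", 1, 300)]
        specs = [("chr1", 30, "AAAAAAAAAAAAA"), ("chr1", 34, "CCCCCCCCCCCCC")]
        hist = position_histogram(annotate(specs, repeats), bin_width=10)
        assert hist.to_dict() == {31: 2}
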