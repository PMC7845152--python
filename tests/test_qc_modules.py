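"""Analysis-module postprocessing: statistics, tables and grading rules."""

import numpy as np
import pytest

from readqc.config import AdapterSet, ContaminantSet, load_limits
from readqc.qc_modules import (FAIL, PASS, WARN, _percentile, adapter_content,
                               basic_statistics, compute_modules,
                               duplication_levels, gc_theoretical, grade,
                               length_distribution, overrepresented_sequences,
                               per_base_content, per_base_n, per_base_quality,
                               per_sequence_gc, per_sequence_quality,
                               per_tile_quality)
from readqc.seqio import SANGER

from conftest import qstr, stats_from

LIMITS = load_limits()


def module_named(mods, name):
    for m in mods:
        if m.name == name:
            return m
    return None


class TestGradeRule:
    def test_low_is_bad_past_error(self):
        assert grade(4, 10, 5, "low-is-bad") == FAIL

    def test_low_is_bad_between(self):
        assert grade(7, 10, 5, "low-is-bad") == WARN

    def test_exactly_at_threshold_not_triggered(self):
        assert grade(10, 10, 5, "low-is-bad") == PASS
        assert grade(5, 10, 5, "low-is-bad") == WARN
        assert grade(10, 5, 10, "high-is-bad") == WARN
        assert grade(5, 5, 10, "high-is-bad") == PASS


class TestPercentileRule:
    def test_hand_cumulative_median(self):
        # histogram {10:1, 20:1, 30:2}: cum at 20 is 2 >= 50% of 4
        hist = np.zeros(94, dtype=np.int64)
        hist[10], hist[20], hist[30] = 1, 1, 2
        values = np.arange(94)
        assert _percentile(hist, values, 50) == 20

    def test_degenerate_histogram(self):
        hist = np.zeros(94, dtype=np.int64)
        hist[30] = 17
        values = np.arange(94)
        for p in (10, 25, 50, 75, 90):
            assert _percentile(hist, values, p) == 30


class TestPerBaseQuality:
    def test_uniform_quality_passes_with_flat_stats(self):
        stats = stats_from([("ACGT", qstr([30] * 4))] * 5)
        mod = per_base_quality(stats, LIMITS, SANGER)
        assert mod.grade == PASS
        for row in mod.rows:
            assert row[1:] == (30.0, 30.0, 30.0, 30.0, 30.0, 30.0)

    def test_median_22_warns(self):
        stats = stats_from([("ACGT", qstr([30, 30, 30, 22]))] * 4)
        mod = per_base_quality(stats, LIMITS, SANGER)
        assert mod.grade == WARN

    def test_lower_quartile_below_5_fails(self):
        stats = stats_from([("AC", qstr([4, 30])), ("AC", qstr([4, 30])),
                            ("AC", qstr([30, 30])), ("AC", qstr([30, 30]))])
        mod = per_base_quality(stats, LIMITS, SANGER)
        assert mod.grade == FAIL


class TestPerTileQuality:
    def test_single_tile_all_deviations_zero(self):
        stats = stats_from([("ACGT", qstr([30] * 4), "M:1:F:1:2101:1:1")] * 3)
        mod = per_tile_quality(stats, LIMITS, SANGER)
        assert mod.grade == PASS
        assert all(row[2] == 0.0 for row in mod.rows)

    def test_two_tiles_12_apart_deviate_by_6_and_warn(self):
        stats = stats_from([
            ("ACGT", qstr([34] * 4), "M:1:F:1:2101:1:1"),
            ("ACGT", qstr([22] * 4), "M:1:F:1:2102:1:1"),
        ])
        mod = per_tile_quality(stats, LIMITS, SANGER)
        devs = {row[0]: row[2] for row in mod.rows}
        assert devs[2101] == pytest.approx(6.0)
        assert devs[2102] == pytest.approx(-6.0)
        assert mod.grade == WARN

    def test_large_drop_fails(self):
        stats = stats_from([
            ("ACGT", qstr([36] * 4), "M:1:F:1:2101:1:1"),
            ("ACGT", qstr([12] * 4), "M:1:F:1:2102:1:1"),
        ])
        assert per_tile_quality(stats, LIMITS, SANGER).grade == FAIL

    def test_headerless_names_omit_module(self):
        stats = stats_from([("ACGT", "IIII")])
        assert per_tile_quality(stats, LIMITS, SANGER) is None
        mods = compute_modules(stats, LIMITS, SANGER)
        assert module_named(mods, "Per tile sequence quality") is None


class TestPerSequenceQuality:
    def test_single_mode_row(self):
        stats = stats_from([("ACGT", qstr([36] * 4))] * 7)
        mod = per_sequence_quality(stats, LIMITS, SANGER)
        assert mod.rows == [(36, 7)]
        assert mod.grade == PASS

    def test_low_mode_fails(self):
        stats = stats_from([("ACGT", qstr([18] * 4))] * 7)
        assert per_sequence_quality(stats, LIMITS, SANGER).grade == FAIL

    def test_bimodal_graded_on_the_mode(self):
        reads = [("ACGT", qstr([35] * 4))] * 5 + [("ACGT", qstr([18] * 4))] * 3
        mod = per_sequence_quality(stats_from(reads), LIMITS, SANGER)
        assert mod.grade == PASS  # mode at 35 despite low shoulder


class TestPerBaseContent:
    def test_poly_a_fails_at_100_percent_imbalance(self):
        stats = stats_from([("AAAA", qstr([30] * 4))] * 5)
        mod = per_base_content(stats, LIMITS, SANGER)
        assert mod.grade == FAIL
        label, g, a, t, c = mod.rows[0]
        assert (g, a, t, c) == (0.0, 100.0, 0.0, 0.0)

    def test_balanced_composition_passes(self):
        stats = stats_from([("ACGT", qstr([30] * 4)),
                            ("TGCA", qstr([30] * 4)),
                            ("GTAC", qstr([30] * 4)),
                            ("CATG", qstr([30] * 4))])
        mod = per_base_content(stats, LIMITS, SANGER)
        assert mod.grade == PASS
        assert all(v == 25.0 for row in mod.rows for v in row[1:])

    def test_all_n_group_reports_zeros_and_skips_grading(self):
        stats = stats_from([("ACGN", qstr([30] * 4))] * 3)
        mod = per_base_content(stats, LIMITS, SANGER)
        assert mod.rows[3][1:] == (0.0, 0.0, 0.0, 0.0)
        # positions 1-3 are fully skewed, so the all-N group must not mask them
        assert mod.grade == FAIL


class TestPerSequenceGC:
    def test_tight_unimodal_passes(self):
        rng = np.random.default_rng(5)
        reads = []
        for _ in range(2000):
            bases = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
            reads.append((bases, qstr([30] * 100)))
        mod = per_sequence_gc(stats_from(reads), LIMITS, SANGER)
        assert mod.grade == PASS
        assert len(mod.rows) == 101

    def test_strongly_bimodal_fails(self):
        reads = [("G" * 50, qstr([30] * 50))] * 60 + \
                [("A" * 50, qstr([30] * 50))] * 60
        mod = per_sequence_gc(stats_from(reads), LIMITS, SANGER)
        assert mod.grade == FAIL

    def test_single_read_still_emits_101_rows(self):
        mod = per_sequence_gc(stats_from([("ACGT", "IIII")]), LIMITS, SANGER)
        assert len(mod.rows) == 101

    def test_theoretical_curve_sums_to_total_within_1_percent(self):
        rng = np.random.default_rng(11)
        obs = np.zeros(101, dtype=np.int64)
        for gc in rng.binomial(100, 0.45, size=2000):
            obs[gc] += 1
        theo = gc_theoretical(obs)
        assert theo.sum() == pytest.approx(obs.sum(), rel=0.01)


class TestPerBaseN:
    def test_no_n_passes_with_zero_rows(self):
        mod = per_base_n(stats_from([("ACGT", "IIII")] * 3), LIMITS, SANGER)
        assert mod.grade == PASS
        assert all(row[1] == 0.0 for row in mod.rows)

    def test_30_percent_n_at_one_position_fails(self):
        reads = [("ANGT", "IIII")] * 3 + [("AAGT", "IIII")] * 7
        mod = per_base_n(stats_from(reads), LIMITS, SANGER)
        assert mod.rows[1][1] == pytest.approx(30.0)
        assert mod.grade == FAIL

    def test_denominator_is_reads_reaching_the_position(self):
        # N in last base of the single longest read: 1/1 = 100% N there
        reads = [("ACG", "III")] * 4 + [("ACGN", "IIII")]
        mod = per_base_n(stats_from(reads), LIMITS, SANGER)
        assert mod.rows[3][1] == pytest.approx(100.0)


class TestLengthDistribution:
    def test_uniform_length_single_row(self):
        mod = length_distribution(stats_from([("A" * 100, qstr([30] * 100))] * 4),
                                  LIMITS, SANGER)
        assert mod.rows == [("100", 4)]
        assert mod.grade == PASS

    def test_variable_lengths_warn(self):
        reads = [("A" * 99, qstr([30] * 99)), ("A" * 100, qstr([30] * 100))]
        mod = length_distribution(stats_from(reads), LIMITS, SANGER)
        assert mod.grade == WARN
        assert [r[0] for r in mod.rows] == ["99", "100"]

    def test_zero_length_read_fails(self):
        mod = length_distribution(stats_from([("", ""), ("ACGT", "IIII")]),
                                  LIMITS, SANGER)
        assert mod.grade == FAIL


class TestDuplicationLevels:
    def test_all_distinct_reads_pass_at_100_percent(self):
        rng = np.random.default_rng(3)
        reads = [("".join(rng.choice(list("ACGT"), size=20)), qstr([30] * 20))
                 for _ in range(50)]
        mod = duplication_levels(stats_from(reads), LIMITS, SANGER)
        assert mod.extra["Total Deduplicated Percentage"] == pytest.approx(100.0)
        assert mod.grade == PASS

    def test_x3_y1_gives_50_percent(self):
        reads = [("AAAA", "IIII")] * 3 + [("CCCC", "IIII")]
        mod = duplication_levels(stats_from(reads), LIMITS, SANGER)
        assert mod.extra["Total Deduplicated Percentage"] == pytest.approx(50.0)
        # level bins: one distinct seq at level 3, one at level 1
        rows = {r[0]: r for r in mod.rows}
        assert rows["1"][1] == pytest.approx(50.0)   # of deduplicated
        assert rows["1"][2] == pytest.approx(25.0)   # of total
        assert rows["3"][2] == pytest.approx(75.0)

    def test_dominant_sequence_fails(self):
        reads = [("ACGT", "IIII")] * 60 + \
                [(f"{b1}{b2}GG", "IIII") for b1 in "ACGT" for b2 in "ACGT"][:40]
        mod = duplication_levels(stats_from(reads), LIMITS, SANGER)
        assert mod.extra["Total Deduplicated Percentage"] < 50
        assert mod.grade == FAIL


CONTAMINANTS = ContaminantSet([
    ("Spiked Contaminant", "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"),
])


class TestOverrepresented:
    def test_sequence_above_1_percent_listed_and_fails(self):
        rng = np.random.default_rng(9)
        uniq = [("".join(rng.choice(list("ACGT"), size=30)), qstr([30] * 30))
                for _ in range(985)]
        reads = [("T" * 30, qstr([30] * 30))] * 15 + uniq  # 1.5% of 1000
        mod = overrepresented_sequences(stats_from(reads), LIMITS, SANGER,
                                        CONTAMINANTS)
        assert mod.grade == FAIL
        assert mod.rows[0][0] == "T" * 30
        assert mod.rows[0][2] == pytest.approx(1.5)

    def test_nothing_above_threshold_gives_empty_pass(self):
        rng = np.random.default_rng(10)
        reads = [("".join(rng.choice(list("ACGT"), size=30)), qstr([30] * 30))
                 for _ in range(1200)]
        mod = overrepresented_sequences(stats_from(reads), LIMITS, SANGER,
                                        CONTAMINANTS)
        assert mod.rows == []
        assert mod.grade == PASS

    def test_planted_contaminant_prefix_is_annotated(self):
        seq = "AGATCGGAAGAGCACACGTCTGAACT" + "TTTT"  # 26 bp contaminant prefix
        reads = [(seq, qstr([30] * 30))] * 10 + \
                [("ACGTACGTACGTACGTACGTACGTACGTAC", qstr([30] * 30))] * 10
        mod = overrepresented_sequences(stats_from(reads), LIMITS, SANGER,
                                        CONTAMINANTS)
        sources = {row[0]: row[3] for row in mod.rows}
        assert "Spiked Contaminant" in sources[seq]
        assert sources["ACGTACGTACGTACGTACGTACGTACGTAC"] == "No Hit"


ADAPTERS = AdapterSet([("Universal", "AGATCGGAAGAG")])


class TestAdapterContent:
    def test_no_adapters_present_all_zero_pass(self):
        reads = [("ACGT" * 25, qstr([30] * 100))] * 10
        mod = adapter_content(stats_from(reads, adapters=ADAPTERS),
                              LIMITS, SANGER)
        assert mod.grade == PASS
        assert all(v == 0.0 for row in mod.rows for v in row[1:])

    def test_20_percent_from_position_30_fails_with_plateau(self):
        with_adapter = "T" * 29 + "AGATCGGAAGAG" + "T" * 9
        reads = [(with_adapter, qstr([30] * 50))] * 20 + \
                [("C" * 50, qstr([30] * 50))] * 80
        mod = adapter_content(stats_from(reads, adapters=ADAPTERS),
                              LIMITS, SANGER)
        assert mod.grade == FAIL
        vals = {row[0]: row[1] for row in mod.rows}
        assert vals["29"] == 0.0
        assert vals["30"] == pytest.approx(20.0)
        assert vals["39"] == pytest.approx(20.0)  # last reported position

    def test_match_only_in_final_window(self):
        with_adapter = "T" * 38 + "AGATCGGAAGAG"
        reads = [(with_adapter, qstr([30] * 50))] * 10
        mod = adapter_content(stats_from(reads, adapters=ADAPTERS),
                              LIMITS, SANGER)
        vals = {row[0]: row[1] for row in mod.rows}
        assert vals["38"] == 0.0
        assert vals["39"] == pytest.approx(100.0)


class TestBasicStatistics:
    def test_four_reads_of_length_four(self):
        mod = basic_statistics(stats_from([("ACGT", "IIII")] * 4), LIMITS,
                               SANGER, filename="x.fq")
        rows = dict((r[0], r[1]) for r in mod.rows)
        assert rows["Total Sequences"] == 4
        assert rows["Sequence length"] == "4"
        assert rows["%GC"] == "50"
        assert rows["Sequences flagged as poor quality"] == 0
        assert mod.grade == PASS

    def test_empty_input_reports_zero_and_skips_other_modules(self):
        stats = stats_from([])
        mods = compute_modules(stats, LIMITS, SANGER, filename="empty.fq")
        assert [m.name for m in mods] == ["Basic Statistics"]
        rows = dict((r[0], r[1]) for r in mods[0].rows)
        assert rows["Total Sequences"] == 0
        assert rows["Sequence length"] == "0"


class TestKmerContent:
    def test_planted_kmer_tops_table_when_enabled(self):
        limits = load_limits()
        limits.values[("kmer", "ignore")] = 0
        rng = np.random.default_rng(21)
        reads = []
        for _ in range(200):
            bases = list("".join(rng.choice(list("ACGT"), size=40)))
            bases[10:17] = "GATTACA"
            reads.append(("".join(bases), qstr([30] * 40)))
        stats = stats_from(reads, count_kmers=True)
        mods = compute_modules(stats, limits, SANGER)
        kmod = module_named(mods, "Kmer Content")
        assert kmod is not None
        assert kmod.rows[0][0] == "GATTACA"

    def test_disabled_by_default_limits(self):
        stats = stats_from([("ACGTACGTAC", qstr([30] * 10))] * 5,
                           count_kmers=True)
        mods = compute_modules(stats, LIMITS, SANGER)
        assert module_named(mods, "Kmer Content") is None
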