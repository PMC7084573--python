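import numpy as np
import pandas as pd
import pytest

from secistrome.compare import (
    A_SPECIFIC,
    LabeledConstituent,
    B_SPECIFIC,
    SHARED,
    classify_constituents,
    cluster_abundance_ratios,
    correlation_matrix,
    count_cobound,
    motif_composition,
    overlap_se_regions,
    shared_se_constituent_breakdown,
    subcluster_averages,
)
from secistrome.core import CoverageTrack, GenomicInterval, Peak
from secistrome.secall import SECandidate


def _peak(start, end, chrom="chr1", summit=None, score=1.0, name="."):
    return Peak(GenomicInterval(chrom, start, end),
                summit if summit is not None else (start + end) // 2, score, name)


def _cand(start, end, chrom="chr1"):
    return SECandidate(GenomicInterval(chrom, start, end), [_peak(start, min(start + 100, end), chrom)])


class TestClassify:
    def test_overlapping_peaks_merge_to_one_shared(self):
        out = classify_constituents([_peak(100, 300)], [_peak(250, 400)])
        assert [c.label for c in out] == [SHARED]
        assert (out[0].peak.start, out[0].peak.end) == (100, 400)

    def test_non_overlapping_labelled_by_origin(self):
        out = classify_constituents([_peak(0, 100)], [_peak(500, 600)])
        assert sorted(c.label for c in out) == [A_SPECIFIC, B_SPECIFIC]

    def test_swapping_inputs_swaps_specific_labels(self):
        a = [_peak(0, 100), _peak(1000, 1100)]
        b = [_peak(50, 150), _peak(5000, 5100)]
        fwd = {(c.peak.start, c.label) for c in classify_constituents(a, b)}
        swap = {A_SPECIFIC: B_SPECIFIC, B_SPECIFIC: A_SPECIFIC, SHARED: SHARED}
        rev = {(c.peak.start, swap[c.label]) for c in classify_constituents(b, a)}
        assert fwd == rev

    def test_merged_summit_comes_from_stronger_member(self):
        pa, pb = _peak(100, 300, summit=150), _peak(250, 400, summit=320)
        (c,) = classify_constituents([pa], [pb], rpkm_a=[1.0], rpkm_b=[9.0])
        assert c.peak.summit == 320
        (c,) = classify_constituents([pa], [pb], rpkm_a=[9.0], rpkm_b=[1.0])
        assert c.peak.summit == 150

    def test_transitive_merge_across_lines(self):
        a = [_peak(0, 100), _peak(150, 250)]
        b = [_peak(80, 180)]
        out = classify_constituents(a, b)
        assert [c.label for c in out] == [SHARED]
        assert (out[0].peak.start, out[0].peak.end) == (0, 250)

    def test_label_counts_invariant_under_input_permutation(self):
        rng = np.random.default_rng(5)
        a = [_peak(int(s), int(s) + 120) for s in rng.integers(0, 50000, 30)]
        b = [_peak(int(s), int(s) + 120) for s in rng.integers(0, 50000, 30)]
        base = [c.label for c in classify_constituents(a, b)]
        shuffled = [c.label for c in classify_constituents(a[::-1], list(reversed(b)))]
        assert sorted(base) == sorted(shuffled)


class TestSharedSE:
    def test_identical_lists_all_pairs_shared(self):
        ses = [_cand(0, 10_000), _cand(50_000, 60_000)]
        pairs, hulls = overlap_se_regions(ses, ses)
        assert len(pairs) == 2 and len(hulls) == 2

    def test_disjoint_lists_empty(self):
        pairs, hulls = overlap_se_regions([_cand(0, 1000)], [_cand(5000, 6000)])
        assert pairs == [] and hulls == []

    def test_one_a_two_b_gives_two_pairs_one_hull(self):
        a = [_cand(0, 10_000)]
        b = [_cand(9_000, 20_000), _cand(30_000, 40_000)]
        pairs, hulls = overlap_se_regions(a, b)
        assert len(pairs) == 1  # the 30-40k B region overlaps nothing
        assert [(h.start, h.end) for h in hulls] == [(0, 20_000)]

    def test_a_bridging_two_b_regions_merges_hull(self):
        a = [_cand(0, 35_000)]
        b = [_cand(9_000, 20_000), _cand(30_000, 40_000)]
        pairs, hulls = overlap_se_regions(a, b)
        assert len(pairs) == 2
        assert [(h.start, h.end) for h in hulls] == [(0, 40_000)]


class TestBreakdown:
    def _cons(self):
        mk = lambda s, lab: LabeledConstituent(_peak(s, s + 100), lab)
        return [mk(100, A_SPECIFIC), mk(300, A_SPECIFIC), mk(500, A_SPECIFIC), mk(700, SHARED)]

    def test_counts_per_hull(self):
        hull = GenomicInterval("chr1", 0, 1000)
        table, totals = shared_se_constituent_breakdown([hull], self._cons())
        assert (totals[A_SPECIFIC], totals[SHARED], totals[B_SPECIFIC]) == (3, 1, 0)

    def test_summit_at_hull_end_excluded(self):
        hull = GenomicInterval("chr1", 0, 750)  # summit of the SHARED peak = 750
        _, totals = shared_se_constituent_breakdown([hull], self._cons())
        assert totals[SHARED] == 0

    def test_totals_equal_sum_over_hulls(self):
        hulls = [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 400, 1000)]
        table, totals = shared_se_constituent_breakdown(hulls, self._cons())
        assert table[["n_a_specific", "n_shared", "n_b_specific"]].sum().sum() == sum(totals.values())


def _density_df():
    rng = np.random.default_rng(0)
    base = rng.gamma(2.0, 5.0, size=20)
    return pd.DataFrame(
        {
            "x": base,
            "x_copy": base,
            "anti": np.where(base > np.median(base), 0.1, 50.0),
            "flat": np.ones(20),
        }
    )


class TestCorrelation:
    def test_identical_columns_correlate_perfectly(self):
        corr = correlation_matrix(_density_df())
        assert corr.loc["x", "x_copy"] == pytest.approx(1.0)

    def test_opposed_pattern_negative(self):
        corr = correlation_matrix(_density_df())
        assert corr.loc["x", "anti"] < 0

    def test_symmetric_with_unit_diagonal(self):
        corr = correlation_matrix(_density_df())
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.all(np.diag(corr.values) == 1.0)

    def test_zero_variance_column_is_nan_not_zero(self):
        corr = correlation_matrix(_density_df())
        assert np.isnan(corr.loc["flat", "x"])

    def test_subcluster_average_is_member_mean(self):
        df = _density_df()
        labels = ["g1"] * 10 + ["g2"] * 10
        means = subcluster_averages(df, labels)
        assert means.loc["g1", "x"] == pytest.approx(df["x"][:10].mean())


class TestCobind:
    def _labeled(self, starts):
        return [LabeledConstituent(_peak(int(s), int(s) + 200), A_SPECIFIC) for s in starts]

    def test_two_collaborators_count_as_cobound(self):
        cons = self._labeled([1000])
        collab = {"TF1": [_peak(950, 1150)], "TF2": [_peak(1050, 1250)]}
        res = count_cobound(cons, collab, min_tfs=2, halfwidth=100)
        assert res["frac_cobound"] == 1.0

    def test_single_collaborator_in_complement(self):
        cons = self._labeled([1000])
        collab = {"TF1": [_peak(950, 1150)], "TF2": [_peak(90_000, 90_200)]}
        res = count_cobound(cons, collab, min_tfs=2, halfwidth=100)
        assert (res["frac_cobound"], res["frac_below"]) == (0.0, 1.0)

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(1)
        cons = self._labeled(list(rng.integers(0, 100_000, 25)))
        collab = {
            f"TF{i}": [_peak(int(s), int(s) + 300) for s in rng.integers(0, 100_000, 15)]
            for i in range(3)
        }
        res = count_cobound(cons, collab, min_tfs=2, halfwidth=100)
        assert res["frac_cobound"] + res["frac_below"] == pytest.approx(1.0)


class TestComposition:
    def test_categories_and_percent_normalisation(self):
        presence = {"r1": {"ERE"}, "r2": {"ERE", "TEAD"}, "r3": set(), "r4": {"TEAD"}}
        table, combos = motif_composition(
            {SHARED: ["r1", "r2", "r3", "r4"]}, presence, ["ERE", "TEAD"]
        )
        row = table.loc[SHARED]
        assert row["ERE"] == pytest.approx(25.0)
        assert row["multiple"] == pytest.approx(25.0)
        assert row["none"] == pytest.approx(25.0)
        assert combos[SHARED]["ERE+TEAD"] == 1
        cats = [c for c in table.columns if c != "n"]
        assert row[cats].sum() == pytest.approx(100.0, abs=0.1)

    def test_swapping_labels_transposes_panels(self):
        presence = {"a1": {"FOX"}, "b1": {"TEAD"}}
        t1, _ = motif_composition(
            {A_SPECIFIC: ["a1"], B_SPECIFIC: ["b1"]}, presence, ["FOX", "TEAD"]
        )
        t2, _ = motif_composition(
            {A_SPECIFIC: ["b1"], B_SPECIFIC: ["a1"]}, presence, ["FOX", "TEAD"]
        )
        assert t1.loc[A_SPECIFIC, "FOX"] == t2.loc[B_SPECIFIC, "FOX"]


def test_cluster_abundance_ratio_code_path():
    a_over_shared, b_over_shared = cluster_abundance_ratios(6, 3, 9)
    assert (a_over_shared, b_over_shared) == (2.0, 3.0)
    with pytest.raises(ValueError):
        cluster_abundance_ratios(1, 0, 1)
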