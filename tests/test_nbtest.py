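import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from smallder import (
    CountMatrix,
    CoverageSet,
    GlobalParams,
    SampleRecord,
    bh_adjust,
    estimate_dispersions,
    nb_wald_test,
    per_nucleotide_pvalues,
    size_factors,
)
from smallder.rle import RunLengthTrack

from oracles import bh_stepup


def nb_counts(rng, mean, alpha, size):
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mean), size=size).astype(float)


def two_group(counts):
    n = counts.shape[1]
    return CountMatrix(counts, np.array(["a"] * (n // 2) + ["b"] * (n - n // 2)))


class TestSizeFactors:
    def test_hand_computed_two_sample_example(self):
        cm = two_group(np.array([[2.0, 4.0], [4.0, 8.0], [6.0, 12.0]]))
        np.testing.assert_allclose(
            size_factors(cm), [0.70710678, 1.41421356], atol=1e-3
        )

    def test_identical_columns_give_unit_factors(self):
        cm = two_group(np.tile([[3.0], [8.0]], (1, 4)))
        np.testing.assert_allclose(size_factors(cm), np.ones(4))

    def test_doubling_a_column_doubles_its_relative_factor(self, rng):
        # scale equivariance: doubling one sample's depth doubles its factor
        # relative to every other sample's
        k = rng.integers(1, 50, (30, 4)).astype(float)
        f1 = size_factors(two_group(k))
        k2 = k.copy()
        k2[:, 2] *= 2
        f2 = size_factors(two_group(k2))
        np.testing.assert_allclose(
            (f2[2] / f2[0]) / (f1[2] / f1[0]), 2.0, rtol=1e-9
        )

    def test_cpm_fallback_when_no_all_positive_feature(self):
        k = np.array([[0.0, 5.0, 5.0, 5.0], [5.0, 0.0, 5.0, 5.0]])
        with pytest.warns(UserWarning, match="CPM"):
            f = size_factors(two_group(k))
        assert np.all(f > 0)

    def test_matches_pydeseq2_median_of_ratios(self, rng):
        import pandas as pd
        from pydeseq2.dds import DeseqDataSet

        k = nb_counts(rng, 100, 0.1, (50, 12))
        dds = DeseqDataSet(
            counts=pd.DataFrame(k.T.astype(int)),
            metadata=pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6}),
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(
            size_factors(two_group(k)),
            np.asarray(dds.obs["size_factors"]),
            rtol=1e-6,
        )


class TestDispersions:
    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        k = rng.poisson(80, size=(50, 40)).astype(float)
        cm = two_group(k)
        d = estimate_dispersions(cm, size_factors(cm))
        assert d.mean() <= 0.05

    def test_recovers_simulated_dispersion(self, rng):
        k = nb_counts(rng, 100, 0.2, (200, 12))
        cm = two_group(k)
        d = estimate_dispersions(cm, size_factors(cm))
        assert 0.1 <= d.mean() <= 0.4

    def test_constant_feature_hits_lower_clamp(self):
        k = np.vstack([np.full(6, 9.0), [1, 5, 9, 2, 8, 4]])
        cm = two_group(k)
        d = estimate_dispersions(cm, np.ones(6))
        assert d[0] < d[1]
        assert d[0] < 0.05

    def test_single_replicate_falls_back_to_trend(self, rng):
        k = nb_counts(rng, 50, 0.1, (20, 2))
        cm = CountMatrix(k, np.array(["a", "b"]))
        with pytest.warns(UserWarning, match="trend"):
            d = estimate_dispersions(cm, np.ones(2))
        assert np.all(d >= 0)


class TestWald:
    def test_identical_counts_in_both_conditions(self):
        k = np.tile([[7.0]], (3, 6))
        res = nb_wald_test(two_group(k), sf=np.ones(6))
        np.testing.assert_array_equal(res.p_value, 1.0)
        np.testing.assert_array_equal(res.log2_fold_change, 0.0)

    def test_all_zero_feature_gets_p_one(self, rng):
        k = nb_counts(rng, 50, 0.1, (5, 6))
        k[2] = 0.0
        res = nb_wald_test(two_group(k), sf=np.ones(6))
        assert res.p_value[2] == 1.0
        assert res.log2_fold_change[2] == 0.0

    def test_null_type_one_error_rate(self, rng):
        k = nb_counts(rng, 100, 0.1, (2000, 12))
        res = nb_wald_test(two_group(k))
        assert abs((res.p_value < 0.05).mean() - 0.05) <= 0.02

    def test_null_pvalues_are_uniform(self, rng):
        """Under the null the p-value distribution should be uniform."""
        k = nb_counts(rng, 100, 0.1, (2000, 12))
        res = nb_wald_test(two_group(k))
        assert kstest(res.p_value, "uniform").pvalue > 0.01

    def test_detects_a_twofold_change(self, rng):
        k = nb_counts(rng, 100, 0.05, (200, 12))
        k[150:, 6:] = nb_counts(rng, 200, 0.05, (50, 6))
        res = nb_wald_test(two_group(k))
        assert (res.p_value[150:] < 0.05).mean() > 0.85
        # with a quarter of the features shifted up, median-of-ratios
        # normalization absorbs a little of the fold change
        assert abs(res.log2_fold_change[150:].mean() - 1.0) < 0.25

    def test_invariant_to_sample_order_and_label_swap(self, rng):
        k = nb_counts(rng, 60, 0.1, (40, 8))
        conds = np.array(["a", "b"] * 4)
        cm = CountMatrix(k, conds)
        sf = size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        res = nb_wald_test(cm, sf, disp)
        perm = np.array([3, 0, 6, 2, 5, 1, 7, 4])
        res_p = nb_wald_test(CountMatrix(k[:, perm], conds[perm]), sf[perm], disp)
        np.testing.assert_allclose(res_p.p_value, res.p_value, atol=1e-12)
        swapped = np.where(conds == "a", "b", "a")
        res_s = nb_wald_test(CountMatrix(k, swapped), sf, disp)
        np.testing.assert_allclose(res_s.p_value, res.p_value, atol=1e-12)
        np.testing.assert_allclose(
            res_s.log2_fold_change, -res.log2_fold_change, atol=1e-10
        )

    def test_pvalue_ranking_agrees_with_pydeseq2(self, rng):
        import pandas as pd
        from scipy.stats import spearmanr
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        mu = np.full(300, 80.0)
        mu[250:] *= 2.5
        ka = nb_counts(rng, 80, 0.1, (300, 6))
        kb = nb_counts(rng, mu[:, None], 0.1, (300, 6))
        k = np.hstack([ka, kb])
        dds = DeseqDataSet(
            counts=pd.DataFrame(k.T.astype(int)),
            metadata=pd.DataFrame({"condition": ["A"] * 6 + ["B"] * 6}),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stat.summary()
        res = nb_wald_test(two_group(k))
        rho = spearmanr(res.p_value, stat.results_df["pvalue"].values).statistic
        assert rho > 0.95


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.2], [0.2]),
            ([0.04, 0.5], [0.08, 0.5]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected)

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_equals_textbook_stepup(self, p):
        np.testing.assert_allclose(bh_adjust(np.array(p)), bh_stepup(p), atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=500)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestPerNucleotide:
    def _cov(self, per_sample_tracks, conds):
        samples = [
            SampleRecord("x", f"s{i}", c) for i, c in enumerate(conds)
        ]
        tracks = {
            f"s{i}": {"chr1": t} for i, t in enumerate(per_sample_tracks)
        }
        length = per_sample_tracks[0].total_length
        libs = {f"s{i}": 1_000_000 for i in range(len(conds))}
        return CoverageSet(samples, {"chr1": length}, tracks, libs)

    def test_low_sum_positions_get_p_one(self):
        # total coverage 1 (< 10) everywhere -> constant 1, no test run
        tracks = [RunLengthTrack("chr1", [0.0, 1.0], [50, 50]) for _ in range(6)]
        tracks[0] = RunLengthTrack("chr1", [0.0], [100])
        cov = self._cov(tracks, ["a"] * 3 + ["b"] * 3)
        mask = RunLengthTrack("chr1", [1.0], [100])
        p = per_nucleotide_pvalues(cov, mask, GlobalParams(), "chr1")
        assert list(p) == [(1.0, 100)]

    def test_identical_count_vectors_share_one_test(self, rng):
        base = rng.integers(20, 40, 6).astype(float)
        vals = []
        for s in range(6):
            v = np.zeros(300)
            v[40:60] = base[s]          # locus 1
            v[200:220] = base[s]        # locus 2: identical count vector
            v[100:130] = base[s] * (4 if s >= 3 else 1)  # a DE locus between
            vals.append(RunLengthTrack.from_array("chr1", v))
        cov = self._cov(vals, ["a"] * 3 + ["b"] * 3)
        mask = RunLengthTrack("chr1", [1.0], [300])
        p = per_nucleotide_pvalues(cov, mask, GlobalParams(), "chr1")
        arr = p.to_array()
        assert arr[45] == arr[210]  # same vector -> same adjusted p
        assert arr[110] < arr[45]   # the perturbed locus scores better
        assert np.all(arr[:40] == 1.0)

    def test_masked_positions_are_forced_to_one(self, rng):
        tracks = [
            RunLengthTrack("chr1", [30.0], [100]) for _ in range(6)
        ]
        cov = self._cov(tracks, ["a"] * 3 + ["b"] * 3)
        mask = RunLengthTrack("chr1", [0.0, 1.0], [60, 40])
        p = per_nucleotide_pvalues(cov, mask, GlobalParams(), "chr1")
        arr = p.to_array()
        assert np.all(arr[:60] == 1.0)

    def test_collapsing_rows_matches_per_row_testing(self, rng):
        """Testing unique count vectors once must reproduce per-row results."""
        k = nb_counts(rng, 50, 0.1, (30, 6))
        k = np.repeat(k, 3, axis=0)  # every row appears 3x
        cm_full = two_group(k)
        sf = size_factors(cm_full)
        uniq, inverse = np.unique(k, axis=0, return_inverse=True)
        cm_uniq = CountMatrix(uniq, cm_full.conditions)
        disp_u = estimate_dispersions(cm_uniq, sf)
        res_u = nb_wald_test(cm_uniq, sf, disp_u)
        res_f = nb_wald_test(cm_full, sf, disp_u[inverse])
        np.testing.assert_allclose(
            res_u.p_value[inverse], res_f.p_value, atol=1e-12
        )


def test_count_matrix_validation():
    with pytest.raises(ValueError, match="two condition"):
        CountMatrix(np.ones((2, 3)), np.array(["a", "a", "a"]))
    with pytest.raises(ValueError, match="non-negative"):
        CountMatrix(np.array([[-1.0, 2.0]]), np.array(["a", "b"]))
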