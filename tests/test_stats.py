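"""Bootstrap Welch test, Kruskal-Wallis/Dunn/BH, Yates chi-square."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from isoreads.stats import (
    DegenerateDataError,
    benjamini_hochberg,
    chi_square_yates,
    kruskal_dunn,
    welch_t_bootstrap,
)


class TestWelchBootstrap:
    def test_identical_samples_give_null_result(self):
        x = np.arange(10.0)
        res = welch_t_bootstrap(x, x.copy(), n_boot=2000, seed=1)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value > 0.9

    def test_statistic_matches_analytic_welch(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(1, 2, 25)
        res = welch_t_bootstrap(x, y, n_boot=100, seed=2)
        want = sps.ttest_ind(x, y, equal_var=False).statistic
        assert res.statistic == pytest.approx(want, rel=1e-12)

    def test_large_effect_is_detected(self, rng):
        x, y = rng.normal(0, 1, 50), rng.normal(3, 1, 50)
        res = welch_t_bootstrap(x, y, n_boot=10_000, seed=3)
        assert res.p_value < 0.001

    def test_p_value_never_exactly_zero(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(10, 1, 20)
        res = welch_t_bootstrap(x, y, n_boot=1000, seed=4)
        assert res.p_value >= 1.0 / 1001

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_t_bootstrap([1.0, 1.0, 1.0], [2.0, 2.0], n_boot=100, seed=5)

    def test_reproducible_for_fixed_seed(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 2, 18)
        r1 = welch_t_bootstrap(x, y, n_boot=5000, seed=9)
        r2 = welch_t_bootstrap(x, y, n_boot=5000, seed=9)
        assert r1.p_value == r2.p_value


class TestKruskalDunn:
    def test_identical_constant_groups_give_zero_h(self):
        res = kruskal_dunn([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_fully_separated_groups_reach_maximal_h(self):
        res = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        # mean ranks 2, 5, 8 without ties: H = 12/(9*10) * 3*(4+25+64) - 30
        assert res.statistic == pytest.approx(7.2)
        want = sps.kruskal([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert res.statistic == pytest.approx(want.statistic)

    def test_h_and_p_match_scipy_on_random_tied_data(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 6))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(4, 15))).astype(float)
                for _ in range(k)
            ]
            res = kruskal_dunn(groups)
            want = sps.kruskal(*groups)
            assert abs(res.statistic - want.statistic) < 1e-8
            assert abs(res.p_value - want.pvalue) < 1e-6

    def test_dunn_z_matches_independent_computation(self, rng):
        """Pairwise z re-derived from pandas mid-ranks and the tie term."""
        for _ in range(50):
            k = int(rng.integers(3, 5))
            groups = [
                rng.integers(0, 6, size=int(rng.integers(4, 12))).astype(float)
                for _ in range(k)
            ]
            res = kruskal_dunn(groups)
            pooled = pd.Series(np.concatenate(groups))
            ranks = pooled.rank(method="average")
            ns = [len(g) for g in groups]
            edges = np.cumsum([0] + ns)
            rbar = [ranks[edges[i]:edges[i + 1]].mean() for i in range(k)]
            n = len(pooled)
            ties = pooled.value_counts()
            tie_term = float(((ties**3) - ties).sum())
            var = n * (n + 1) / 12 - tie_term / (12 * (n - 1))
            for row, (i, j) in zip(
                res.pairwise.itertuples(), combinations(range(k), 2)
            ):
                z = (rbar[i] - rbar[j]) / np.sqrt(var * (1 / ns[i] + 1 / ns[j]))
                assert row.z == pytest.approx(z, abs=1e-10)
                assert row.p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_bh_adjustment_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 20)))
            want = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(benjamini_hochberg(p), want, atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateDataError):
            kruskal_dunn([[1, 2], [], [3, 4]])


class TestChiSquareYates:
    def test_balanced_table_gives_zero(self):
        res = chi_square_yates([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_exon2_splicing_table_is_highly_significant(self):
        # 6788 of 29,177 alternatively spliced vs 5378 of 85,860
        res = chi_square_yates([[6788, 29177 - 6788], [5378, 85860 - 5378]])
        assert res.p_value < 0.0001

    def test_matches_scipy_contingency_with_correction(self, rng):
        checked = 0
        while checked < 50:
            t = rng.poisson(40, size=(2, 2)) + 1
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            if np.abs(t - expected).min() < 0.6:
                continue  # scipy's correction can overshoot tiny deviations
            res = chi_square_yates(t)
            want = sps.chi2_contingency(t, correction=True)
            assert abs(res.statistic - want.statistic) < 1e-8
            assert abs(res.p_value - want.pvalue) < 1e-8
            checked += 1

    def test_small_deviation_clamped_to_zero(self):
        # |O - E| = 0.25 < 0.5 in every cell: statistic must clamp to 0
        res = chi_square_yates([[10, 10], [10, 11]])
        assert res.statistic == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_yates([[0, 0], [5, 10]])


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.042])[0] == pytest.approx(0.042)

    def test_uniform_ladder_collapses_to_largest(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1,
                 max_size=30)
    )
    @settings(max_examples=200, deadline=None)
    def test_adjusted_at_least_raw_and_rank_monotone(self, p):
        p = np.array(p)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)
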