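import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from icas_hemoflow import (
    bonferroni_adjust,
    chi_square_independence,
    cohen_kappa,
    friedman_test,
    pairwise_posthoc,
    partial_spearman,
    spearman_rank,
    threshold_split_correlation,
    wilcoxon_signed_rank,
)
from icas_hemoflow.errors import (
    ConstantInputError,
    InputError,
    StatisticsError,
    SubgroupSizeError,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rank(range(1, 6), range(5, 0, -1)).r_s == -1.0
        assert spearman_rank([1, 2, 3, 4], [1, 2, 3, 4]).r_s == 1.0

    def test_tied_data_matches_hand_ranks(self):
        # ranks of x = (1, 2.5, 2.5, 4); y identical ordering with ties
        res = spearman_rank([1, 2, 2, 3], [10, 20, 20, 40])
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        expected = np.corrcoef(rx, rx)[0, 1]
        assert res.r_s == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=12,
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_matches_scipy(self, x):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(x))
        res = spearman_rank(x, y)
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, perm):
        x = np.array(perm, float)
        y = np.arange(6.0)
        a = spearman_rank(x, y).r_s
        b = spearman_rank(np.exp(x), y ** 3 + 5).r_s
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman_rank([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_exact_and_permutation_p_agree(self):
        x = [3, 1, 4, 1.5, 5, 9]
        y = [2, 7, 1, 8, 2.5, 8.5]
        exact = spearman_rank(x, y, p_method="exact").p_value
        perm = spearman_rank(x, y, p_method="permutation", n_perm=20000,
                             seed=5).p_value
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(perm - exact) < 4 * se + 1e-4


class TestPartialSpearman:
    def test_constant_covariate_reduces_to_plain(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        plain = spearman_rank(x, y).r_s
        part = partial_spearman(x, y, np.ones((20, 1))).r_s
        assert part == pytest.approx(plain, abs=1e-12)

    def test_fully_explained_by_covariate(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=30)
        x = rng.normal(size=30)
        res = partial_spearman(x, z, z.reshape(-1, 1))
        assert abs(res.r_s) < 1e-8

    def test_small_worked_example_matches_lstsq_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        z = np.array([1.0, 1, 2, 2, 3, 3])
        res = partial_spearman(x, y, z.reshape(-1, 1))
        # independent residualize-then-correlate computation on ranks
        rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
        Z = np.column_stack([np.ones(6), rz])
        ex = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ey = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
        expected = np.corrcoef(ex, ey)[0, 1]
        assert res.r_s == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "x": rng.normal(size=40), "y": rng.normal(size=40),
            "z1": rng.normal(size=40), "z2": rng.normal(size=40)})
        df["y"] += 0.5 * df["z1"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"],
                                    method="spearman")
        res = partial_spearman(df.x, df.y, df[["z1", "z2"]].to_numpy())
        assert res.r_s == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_collinear_covariates_rejected(self):
        from icas_hemoflow.errors import DegenerateAdjustmentError
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(size=15)
        z = rng.normal(size=15)
        with pytest.raises(DegenerateAdjustmentError):
            partial_spearman(x, y, np.column_stack([z, 2 * z]))


class TestFriedman:
    def test_identical_columns_null(self):
        X = np.tile([[1.0, 1.0, 1.0]], (5, 1))
        res = friedman_test(X)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_perfectly_consistent_ranks(self):
        """Five blocks each ranked (1, 2, 3): Q = 10, p = exp(-5)."""
        X = np.tile([[1.0, 2.0, 3.0]], (5, 1))
        res = friedman_test(X)
        assert res.statistic == pytest.approx(10.0, abs=1e-12)
        assert res.p_value == pytest.approx(np.exp(-5.0), rel=1e-9)
        assert res.df == 2

    @given(seed=st.integers(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 5, size=(6, 4)).astype(float)  # with ties
        if any(len(np.unique(row)) == 1 for row in X):
            X += rng.normal(0, 1e-6, X.shape)
        res = friedman_test(X)
        ref = sps.friedmanchisquare(*[X[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monotone_within_block_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 3))
        a = friedman_test(X).statistic
        b = friedman_test(np.exp(X)).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_permutation_p_close_to_chi2_for_moderate_n(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 3))
        chi2_p = friedman_test(X).p_value
        perm_p = friedman_test(X, p_method="permutation", n_perm=4000,
                               seed=1).p_value
        assert abs(chi2_p - perm_p) < 0.08

    def test_missing_cells_rejected(self):
        X = np.ones((4, 3))
        X[1, 2] = np.nan
        with pytest.raises(InputError):
            friedman_test(X)


class TestBonferroni:
    def test_definition_and_cap(self):
        assert bonferroni_adjust([0.01, 0.04]) == [0.02, 0.08]
        assert bonferroni_adjust([0.9, 0.9]) == [1.0, 1.0]
        assert bonferroni_adjust([0.3]) == [0.3]

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            bonferroni_adjust([0.5, 1.2])


class TestWilcoxon:
    def test_identical_pairs_give_p_one(self):
        res = wilcoxon_signed_rank(np.ones(8), np.ones(8))
        assert res.p_value == 1.0

    def test_uniform_shift_exact_p(self):
        """All ten differences positive: two-sided exact p = 2 / 2^10."""
        x = np.arange(10.0)
        res = wilcoxon_signed_rank(x + np.linspace(5, 6, 10), x)
        assert res.extra["method"] == "exact"
        assert res.p_value == pytest.approx(2.0 / 1024.0, rel=1e-12)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(size=12)
        d = d[d != 0]
        if len(np.unique(np.abs(d))) < len(d):
            return
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_posthoc_bonferroni_arithmetic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        X[:, 2] += 10.0
        results = pairwise_posthoc(X)
        assert len(results) == 3
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))

    def test_posthoc_gate_on_friedman(self):
        rng = np.random.default_rng(9)
        X = np.tile(rng.normal(size=(6, 1)), (1, 3))  # identical columns
        with pytest.raises(StatisticsError):
            pairwise_posthoc(X, require_friedman=True)


class TestChiSquare:
    def test_hand_computed_2x2(self):
        res = chi_square_independence([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert res.df == 1

    def test_proportional_rows_independent(self):
        res = chi_square_independence([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_df_formula(self):
        res = chi_square_independence(np.ones((4, 2)))
        assert res.df == 3

    def test_matches_scipy(self):
        T = np.array([[12, 5, 9], [3, 14, 10]])
        res = chi_square_independence(T)
        ref = sps.chi2_contingency(T, correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi_square_independence([[0, 0], [5, 5]])


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([[10, 0], [0, 10]]).statistic == pytest.approx(1.0)

    def test_hand_computed_value(self):
        res = cohen_kappa([[20, 5], [10, 15]])
        assert res.statistic == pytest.approx(0.4, abs=1e-12)
        assert res.extra["p_observed"] == pytest.approx(0.7)
        assert res.extra["p_expected"] == pytest.approx(0.5)

    def test_chance_level_is_zero(self):
        # observed diagonal equals the expected-by-chance agreement
        res = cohen_kappa([[9, 21], [21, 49]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, 60)
        b = np.where(rng.uniform(size=60) < 0.8, a, 1 - a)
        T = np.zeros((2, 2))
        for i, j in zip(a, b):
            T[i, j] += 1
        assert cohen_kappa(T).statistic == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)


class TestThresholdSplit:
    def test_perfect_monotone_in_both_subgroups(self):
        sten = np.array([20, 25, 30, 35, 40, 55, 60, 65, 70, 75], float)
        idx = sten ** 2
        cov = np.ones((10, 1))
        lo, hi = threshold_split_correlation(sten, idx, cov, cutoff=50.0)
        assert lo.r_s == pytest.approx(1.0)
        assert hi.r_s == pytest.approx(1.0)

    def test_undersized_subgroup_rejected(self):
        sten = np.array([20, 25, 30, 35, 40, 42, 45, 46, 47, 48], float)
        with pytest.raises(SubgroupSizeError):
            threshold_split_correlation(sten, sten, np.ones((10, 1)))
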