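import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from comanet.inference import (
    fit_cca,
    permutation_test_cca,
    r2_change,
    rank_inverse_normal,
    stepwise_regression,
    variate_loadings,
)
from oracles import first_cca_correlation_eig, stepwise_reference


class TestFitCCA:
    def test_single_pair_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        res = fit_cca(x[:, None], y[:, None])
        assert res.canonical_correlations[0] == pytest.approx(
            abs(stats.pearsonr(x, y).statistic), abs=1e-10
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        res = fit_cca(X, X.copy())
        np.testing.assert_allclose(res.canonical_correlations, 1.0, atol=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 2)) + 0.3 * X[:, :2]
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        res1 = fit_cca(X, Y)
        res2 = fit_cca(X @ A, Y)
        np.testing.assert_allclose(
            res1.canonical_correlations, res2.canonical_correlations, atol=1e-8
        )

    def test_matches_generalized_eigen_solution(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        Y = rng.normal(size=(50, 3)) + 0.5 * X[:, :3]
        res = fit_cca(X, Y)
        assert res.canonical_correlations[0] == pytest.approx(
            first_cca_correlation_eig(X, Y), abs=1e-10
        )

    def test_maximality_over_variable_pairs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        Y = rng.normal(size=(60, 3)) + 0.4 * X
        res = fit_cca(X, Y)
        best_pairwise = max(
            abs(stats.pearsonr(X[:, i], Y[:, j]).statistic)
            for i in range(3)
            for j in range(3)
        )
        assert res.canonical_correlations[0] >= best_pairwise - 1e-8

    def test_variates_have_unit_variance_and_match_correlations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 2)) + 0.5 * X[:, :2]
        res = fit_cca(X, Y)
        np.testing.assert_allclose(res.x_variates.std(axis=0, ddof=1), 1.0,
                                   atol=1e-8)
        for k in range(res.n_pairs):
            r = stats.pearsonr(res.x_variates[:, k], res.y_variates[:, k]).statistic
            assert abs(r) == pytest.approx(res.canonical_correlations[k], abs=1e-8)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = 2 * X["a"]
        Y = pd.DataFrame({"y0": rng.normal(size=30), "y1": rng.normal(size=30)})
        with pytest.raises(ValueError, match="b"):
            fit_cca(X, Y)

    def test_too_few_subjects(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="n >"):
            fit_cca(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))


class TestPermutationTest:
    def test_degenerate_self_correlation_p_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        res = permutation_test_cca(X, X.copy(), n_perm=200, seed=1)
        assert res.p_values[0] == 0.0

    def test_p_values_non_decreasing_across_pairs(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3)) + 0.5 * X
        res = permutation_test_cca(X, Y, n_perm=300, seed=2)
        assert np.all(np.diff(res.p_values) >= 0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(30, 2)), rng.normal(size=(30, 2))
        a = permutation_test_cca(X, Y, n_perm=100, seed=3)
        b = permutation_test_cca(X, Y, n_perm=100, seed=3)
        np.testing.assert_array_equal(a.null_max, b.null_max)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(300):
            X = rng.standard_normal((30, 3))
            Y = rng.standard_normal((30, 3))
            res = permutation_test_cca(X, Y, n_perm=100,
                                       seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p_values[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestVariateLoadings:
    def test_identity_rescaling_and_noise(self):
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame({"signal": rng.normal(size=n)})
        Y = pd.DataFrame({
            "copy": X["signal"] + 0.05 * rng.normal(size=n),
            "noise": rng.normal(size=n),
        })
        res = fit_cca(X, Y)
        lo = variate_loadings(res, X, Y)
        copy_loading = lo.loc[lo.variable == "copy", "loading"].iloc[0]
        noise_loading = lo.loc[lo.variable == "noise", "loading"].iloc[0]
        assert abs(copy_loading) > 0.99
        assert abs(noise_loading) < 0.2
        # loadings are correlations, hence scale-invariant
        lo2 = variate_loadings(res, X * 100, Y * 0.01)
        np.testing.assert_allclose(lo["loading"], lo2["loading"], atol=1e-12)


class TestRankInverseNormal:
    def test_three_values_blom(self):
        # independent oracle: plain normal quantiles of (r - 3/8) / (n + 1/4)
        got = rank_inverse_normal([10.0, -5.0, 3.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[1] == pytest.approx(-0.8694, abs=1e-4)
        assert got[2] == pytest.approx(0.0, abs=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30,
                    unique=True))
    def test_monotone_and_antisymmetric(self, values):
        v = np.array(values)
        z = rank_inverse_normal(v)
        assert np.all(np.diff(z[np.argsort(v)]) > 0)
        np.testing.assert_allclose(rank_inverse_normal(-v), -z, atol=1e-12)

    def test_sample_mean_near_zero(self):
        rng = np.random.default_rng(5)
        z = rank_inverse_normal(rng.normal(size=500))
        assert -0.05 < z.mean() < 0.05

    def test_ties_averaged(self):
        z = rank_inverse_normal([1.0, 1.0, 5.0])
        assert z[0] == z[1] < z[2]

    def test_all_equal_error(self):
        with pytest.raises(ValueError, match="all values equal"):
            rank_inverse_normal([2.0, 2.0, 2.0])


def _toy_problem(rng, n=80, k=5):
    X = pd.DataFrame(rng.normal(size=(n, k)),
                     columns=[f"x{i}" for i in range(k)])
    y = 0.8 * X["x0"] + 0.5 * X["x1"] + rng.normal(size=n)
    return y.to_numpy(), X


class TestStepwiseRegression:
    def test_perfect_predictor_selected_alone(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        res = stepwise_regression(X["x1"].to_numpy(), X)
        assert res.selected == ["x1"]
        assert res.betas["x1"] == pytest.approx(1.0, abs=1e-8)

    def test_thresholds_one_reproduce_full_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        y, X = _toy_problem(rng)
        res = stepwise_regression(y, X, entry_p=1.0, removal_p=1.01)
        assert set(res.selected) == set(X.columns)
        full = sm.OLS(y, sm.add_constant(X.to_numpy())).fit()
        assert res.r_squared == pytest.approx(full.rsquared, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_reference_path(self, seed):
        rng = np.random.default_rng(seed)
        y, X = _toy_problem(rng, n=60)
        res = stepwise_regression(y, X)
        ref = stepwise_reference(y, X.to_numpy(), list(X.columns))
        assert res.selected == ref

    def test_termination_invariant(self):
        rng = np.random.default_rng(2)
        y, X = _toy_problem(rng)
        res = stepwise_regression(y, X)
        assert all(p < 0.10 for p in res.p_values.values())
        assert res.adj_r_squared <= res.r_squared

    def test_listwise_deletion_logged(self):
        rng = np.random.default_rng(3)
        y, X = _toy_problem(rng, n=30)
        X.iloc[4, 0] = np.nan
        res = stepwise_regression(y, X)
        assert res.dropped_ids == [4]
        assert res.n_used == 29

    def test_no_entry_flagged_empty(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        res = stepwise_regression(y, X, entry_p=1e-9)
        assert res.empty and res.selected == []


class TestR2Change:
    def test_identity_zero_and_definition(self):
        rng = np.random.default_rng(5)
        y, X = _toy_problem(rng)
        res = stepwise_regression(y, X, entry_p=1.0, removal_p=1.01)
        assert r2_change(res, res.selected) == 0.0
        import statsmodels.api as sm

        reduced = sm.OLS(y, sm.add_constant(X[["x0"]].to_numpy())).fit()
        assert r2_change(res, ["x0"]) == pytest.approx(
            res.r_squared - reduced.rsquared, abs=1e-12
        )

    def test_adding_noise_changes_little(self):
        changes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            X = pd.DataFrame({"x1": rng.normal(size=n),
                              "noise": rng.normal(size=n)})
            y = X["x1"].to_numpy() + rng.normal(size=n)
            res = stepwise_regression(y, X, entry_p=1.0, removal_p=1.01)
            changes.append(r2_change(res, ["x1"]))
        assert all(c >= 0 for c in changes)
        assert np.mean(changes) < 0.05

    def test_non_nested_error(self):
        rng = np.random.default_rng(6)
        y, X = _toy_problem(rng)
        res = stepwise_regression(y, X)
        with pytest.raises(ValueError, match="nested"):
            r2_change(res, ["not_a_predictor"])
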