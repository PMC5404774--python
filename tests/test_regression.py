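import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from snpconsensus.regression import (
    lasso_fit,
    ols_fit,
    partial_f_test,
    ridge_fit,
    stepwise_forward,
    wald_test,
)


def _orthonormal_design(rng, n=60, p=4):
    """Zero-mean columns with X'X = n I (unit sample sd)."""
    q, _ = np.linalg.qr(rng.normal(size=(n, p + 1)))
    q = q[:, 1:]  # drop the component aligned with the intercept
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    return q * np.sqrt(n)


@pytest.fixture
def fixture_50x5(rng):
    x = rng.normal(size=(50, 5))
    beta = np.array([1.0, 0.0, -0.5, 0.2, 0.0])
    y = x @ beta + rng.normal(size=50)
    return x, y


class TestOLS:
    def test_exact_fit_recovers_coefficients(self):
        x = np.arange(1.0, 9.0).reshape(-1, 1)
        fit = ols_fit(x, 2 * x.ravel())
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_orthonormal_design_closed_form(self, rng):
        x = _orthonormal_design(rng)
        y = rng.normal(size=x.shape[0])
        fit = ols_fit(x, y)
        np.testing.assert_allclose(fit.coefficients,
                                   x.T @ (y - y.mean()) / x.shape[0],
                                   atol=1e-8)

    def test_matches_statsmodels(self, fixture_50x5):
        x, y = fixture_50x5
        fit = ols_fit(x, y)
        oracle = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients, oracle.params[1:],
                                   atol=1e-8)
        np.testing.assert_allclose(fit.std_errors, oracle.bse[1:], atol=1e-8)
        assert fit.model_r2 == pytest.approx(oracle.rsquared, abs=1e-10)
        assert fit.model_pvalue == pytest.approx(oracle.f_pvalue, abs=1e-12)

    def test_rank_deficiency_raises(self, rng):
        x = rng.normal(size=(20, 2))
        x = np.hstack([x, x[:, :1]])
        with pytest.raises(np.linalg.LinAlgError):
            ols_fit(x, rng.normal(size=20))


class TestWaldTest:
    def test_null_statistic_gives_p_one(self):
        assert wald_test(0.0, 1.0, 30) == pytest.approx(1.0)

    def test_large_statistic_drives_p_to_zero(self):
        assert wald_test(100.0, 1.0, 30) < 1e-12

    def test_matches_ols_coefficient_t_test(self, fixture_50x5):
        x, y = fixture_50x5
        fit = ols_fit(x, y)
        oracle = sm.OLS(y, sm.add_constant(x)).fit()
        for i in range(5):
            p = wald_test(float(fit.coefficients[i]),
                          float(fit.std_errors[i]), fit.df_resid)
            assert p == pytest.approx(oracle.pvalues[i + 1], abs=1e-10)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0, 10)


class TestPartialFTest:
    def test_identical_models_give_p_one(self, fixture_50x5):
        x, y = fixture_50x5
        fit = ols_fit(x[:, :2], y, names=["a", "b"])
        assert partial_f_test(fit, fit, len(y)) == 1.0

    def test_non_nested_rejected(self, fixture_50x5):
        x, y = fixture_50x5
        small = ols_fit(x[:, :2], y, names=["a", "b"])
        large = ols_fit(x[:, 2:5], y, names=["c", "d", "e"])
        with pytest.raises(ValueError, match="nested"):
            partial_f_test(small, large, len(y))

    def test_matches_statsmodels_nested_comparison(self, fixture_50x5):
        x, y = fixture_50x5
        small = ols_fit(x[:, :2], y, names=["a", "b"])
        large = ols_fit(x[:, :4], y, names=["a", "b", "c", "d"])
        p = partial_f_test(small, large, len(y))
        sm_small = sm.OLS(y, sm.add_constant(x[:, :2])).fit()
        sm_large = sm.OLS(y, sm.add_constant(x[:, :4])).fit()
        _, oracle_p, _ = sm_large.compare_f_test(sm_small)
        assert p == pytest.approx(oracle_p, abs=1e-10)

    def test_null_addition_p_is_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            x = rng.normal(size=(40, 3))
            y = x[:, 0] + rng.normal(size=40)
            small = ols_fit(x[:, :1], y, names=["a"])
            large = ols_fit(x[:, :3], y, names=["a", "b", "c"])
            ps.append(partial_f_test(small, large, 40))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_causal_addition_is_powerful(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 4, size=(460, 2)).astype(float)
        y = x[:, 1] + rng.normal(size=460)  # beta/sigma = 1
        small = ols_fit(x[:, :1], y, names=["a"])
        large = ols_fit(x, y, names=["a", "b"])
        assert partial_f_test(small, large, 460) < 0.001


class TestStepwiseForward:
    def test_constant_response_selects_nothing(self, rng):
        x = rng.normal(size=(30, 5))
        fit, calls = stepwise_forward(x, np.ones(30), list("abcde"))
        assert fit is None and calls == []

    def test_dominant_predictor_enters_first(self, rng):
        x = rng.normal(size=(100, 10))
        y = 3 * x[:, 7] + 0.1 * rng.normal(size=100)
        # oracle: the first entry must be the candidate with the best
        # single-predictor RSS, found by enumeration
        rss = [np.sum(sm.OLS(y, sm.add_constant(x[:, [j]])).fit().resid ** 2)
               for j in range(10)]
        assert int(np.argmin(rss)) == 7
        fit, calls = stepwise_forward(x, y, [f"v{j}" for j in range(10)])
        assert fit.names[0] == "v7"
        assert calls[0].snp_id == "v7" and calls[0].significant

    def test_duplicate_column_enters_once(self, rng):
        x = rng.normal(size=(80, 3))
        x[:, 2] = x[:, 0]
        y = 2 * x[:, 0] + 0.3 * rng.normal(size=80)
        fit, _ = stepwise_forward(x, y, ["a", "b", "dup"])
        assert sum(name in {"a", "dup"} for name in fit.names) == 1

    def test_flags_respect_cutoff(self, rng):
        x = rng.normal(size=(60, 6))
        y = x[:, 0] + rng.normal(size=60)
        _, calls = stepwise_forward(x, y, [f"v{j}" for j in range(6)])
        for c in calls:
            assert c.significant == (c.statistic <= 0.01)


class TestRidge:
    def test_lambda_zero_equals_ols(self, fixture_50x5):
        x, y = fixture_50x5
        ols = ols_fit(x, y)
        fit, _ = ridge_fit(x, y, lambda_=0.0)
        np.testing.assert_allclose(fit.coefficients, ols.coefficients,
                                   atol=1e-8)
        assert fit.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_infinite_lambda_predicts_the_mean(self, fixture_50x5):
        x, y = fixture_50x5
        fit, _ = ridge_fit(x, y, lambda_=1e12)
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-8)
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-6)

    def test_orthonormal_shrinkage_identity(self, rng):
        x = _orthonormal_design(rng)
        y = rng.normal(size=x.shape[0])
        lam_unit = 2.5  # on the X'X = nI scale
        ols = ols_fit(x, y)
        fit, _ = ridge_fit(x, y, lambda_=lam_unit * x.shape[0])
        np.testing.assert_allclose(fit.coefficients,
                                   ols.coefficients / (1 + lam_unit),
                                   atol=1e-8)

    def test_gcv_selects_finite_lambda_and_flags_cutoff(self, fixture_50x5):
        x, y = fixture_50x5
        fit, calls = ridge_fit(x, y)
        assert fit.lambda_ > 0
        assert len(calls) == 5
        for c in calls:
            assert c.significant == (c.statistic <= 0.01)


class TestLasso:
    def test_huge_penalty_zeroes_every_coefficient(self, fixture_50x5):
        x, y = fixture_50x5
        fit, calls = lasso_fit(x, y, lambda_=1e6)
        np.testing.assert_allclose(fit.coefficients, 0.0)
        assert calls == []
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-8)

    def test_orthonormal_soft_threshold_identity(self, rng):
        x = _orthonormal_design(rng)
        y = rng.normal(size=x.shape[0]) + x @ np.array([1.0, -0.6, 0.3, 0.0])
        lam = 0.25
        ols_beta = x.T @ (y - y.mean()) / x.shape[0]
        expected = np.sign(ols_beta) * np.maximum(np.abs(ols_beta) - lam, 0)
        fit, _ = lasso_fit(x, y, lambda_=lam)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-6)

    def test_cv_recovers_planted_sparse_signal(self):
        rng = np.random.default_rng(17)
        hits = 0
        for rep in range(5):
            x = rng.integers(1, 4, size=(200, 30)).astype(float)
            y = (0.8 * x[:, 3] - 0.7 * x[:, 11] + 0.9 * x[:, 22]
                 + rng.normal(size=200))
            fit, calls = lasso_fit(x, y, seed=rep,
                                   names=[f"v{j}" for j in range(30)])
            nonzero = {fit.names[j] for j in np.nonzero(fit.coefficients)[0]}
            if {"v3", "v11", "v22"} <= nonzero:
                hits += 1
        assert hits >= 4

    def test_significant_calls_bounded_by_cutoff(self, rng):
        x = rng.integers(1, 4, size=(100, 10)).astype(float)
        y = x[:, 2] + rng.normal(size=100)
        _, calls = lasso_fit(x, y, seed=0)
        assert calls, "expected at least one nonzero coefficient"
        for c in calls:
            assert c.significant == (c.statistic <= 0.01)
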