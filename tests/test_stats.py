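"""Logistic fitting, penalized fitting, NTCP evaluation and metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rionntcp.stats import (DegenerateFitError, FittedLogisticModel, aic_bic,
                            auc_roc, chi_square_test, cross_entropy,
                            fit_logistic, fit_logistic_lasso, hosmer_lemeshow,
                            lasso_lambda_for_max_k, lasso_path_lambdas, ntcp,
                            predict_proba, spearman_rcc)


def _table_design(a, b, c, d):
    """Exposure/outcome rows for a 2x2 table: exposed a events / b non-events,
    unexposed c events / d non-events."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    return x[:, None], y


class TestFitLogistic:
    def test_two_by_two_slope_is_log_odds_ratio(self):
        X, y = _table_design(8, 4, 4, 8)
        m = fit_logistic(X, y)
        assert m.beta[1] == pytest.approx(math.log(4.0), abs=1e-6)

    def test_intercept_only_is_logit_prevalence(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        m = fit_logistic(np.zeros((10, 0)), y)
        assert m.beta[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateFitError):
            fit_logistic(np.arange(6, dtype=float)[:, None], np.ones(6))

    def test_separation_flags_nonconvergence(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()  # perfectly separated
        m = fit_logistic(x[:, None], y)
        assert not m.converged

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 3))
        eta = -1.0 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(ours.log_likelihood, ref.llf, atol=1e-8)
        np.testing.assert_allclose(ours.standard_errors, ref.bse, rtol=1e-4)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(11)
    X = np.column_stack([rng.normal(50, 10, 500), (rng.random(500) < 0.3).astype(float)])
    eta = -3.0 + 0.04 * X[:, 0] + 1.0 * X[:, 1]
    y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestLasso:

    def test_zero_penalty_matches_mle(self, xy):
        X, y = xy
        mle = fit_logistic(X, y)
        lasso = fit_logistic_lasso(X, y, 0.0)
        assert np.max(np.abs(mle.beta - lasso.beta)) < 1e-4

    def test_full_shrinkage(self, xy):
        X, y = xy
        lam_max = lasso_path_lambdas(X, y, 2)[0]
        m = fit_logistic_lasso(X, y, lam_max * 1.001)
        assert np.all(m.beta[1:] == 0.0)
        prev = y.mean()
        assert m.beta[0] == pytest.approx(math.log(prev / (1 - prev)), abs=1e-6)

    def test_duplicated_covariate_splits_coefficient(self, xy):
        X, y = xy
        x0 = X[:, :1]
        single = fit_logistic_lasso(x0, y, 0.01)
        dup = fit_logistic_lasso(np.hstack([x0, x0]), y, 0.01)
        assert dup.beta[1] + dup.beta[2] == pytest.approx(single.beta[1], abs=1e-5)

    def test_against_grid_oracle(self):
        # brute-force maximization of the penalized likelihood on a coarse
        # grid for a 2-parameter (offset + one slope) problem
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + 0.9 * x)))).astype(float)
        xs = (x - x.mean()) / x.std()
        lam = 0.05

        def objective(b0, b1):
            eta = b0 + b1 * xs
            return -np.mean(y * eta - np.logaddexp(0, eta)) + lam * abs(b1)

        grid = np.linspace(-2, 2, 401)
        vals = [(objective(b0, b1), b0, b1) for b0 in grid for b1 in grid]
        _, b0_star, b1_star = min(vals)
        m = fit_logistic_lasso(x[:, None], y, lam)
        assert m.beta_std[0] == pytest.approx(b0_star, abs=0.02)
        assert m.beta_std[1] == pytest.approx(b1_star, abs=0.02)

    def test_shrinkage_is_monotone_along_path(self, xy):
        X, y = xy
        lambdas = lasso_path_lambdas(X, y, 20)
        norms = []
        for lam in lambdas:
            norms.append(np.sum(np.abs(fit_logistic_lasso(X, y, lam).beta_std[1:])))
        assert all(a <= b + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_lambda_for_max_k(self, xy):
        X, y = xy
        # k at least the number of covariates: the path minimum comes back
        path = lasso_path_lambdas(X, y)
        assert lasso_lambda_for_max_k(X, y, 5) == pytest.approx(path[-1])
        # k=1 admits only the dominant covariate
        lam = lasso_lambda_for_max_k(X, y, 1)
        m = fit_logistic_lasso(X, y, lam)
        assert m.n_nonzero_slopes() <= 1


class TestNtcp:
    MODEL = FittedLogisticModel(["age", "hypertension"],
                                np.array([-5.07, 0.031, 1.21]),
                                log_likelihood=-1.0, n_obs=10, n_params=3)

    def test_hand_evaluation_hypertensive(self):
        # eta = -5.07 + 0.031*60 + 1.21 = -2.00
        p = ntcp(self.MODEL, {"age": 60.0, "hypertension": 1.0})
        assert p == pytest.approx(1 / (1 + math.exp(2.0)), abs=1e-3)

    def test_hand_evaluation_normotensive(self):
        p = ntcp(self.MODEL, {"age": 43.0, "hypertension": 0.0})
        assert p == pytest.approx(0.0233, abs=2e-4)

    def test_zero_coefficients_give_half(self):
        m = FittedLogisticModel(["a"], np.zeros(2), log_likelihood=-1.0,
                                n_obs=10, n_params=2)
        assert ntcp(m, {"a": 123.0}) == 0.5

    def test_missing_covariate_named(self):
        with pytest.raises(KeyError, match="hypertension"):
            ntcp(self.MODEL, {"age": 50.0})


class TestMetrics:
    def test_auc_examples(self):
        assert auc_roc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
        assert auc_roc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0
        assert auc_roc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            return
        cases, controls = scores[labels == 1], scores[labels == 0]
        brute = np.mean([(c > d) + 0.5 * (c == d) for c in cases for d in controls])
        assert auc_roc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_cross_entropy_symmetric_case(self):
        assert cross_entropy([0.5, 0.5], [1, 0]) == pytest.approx(math.log(2))

    def test_cross_entropy_equals_nll_per_sample(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.3).astype(float)
        m = fit_logistic(X, y)
        ce = cross_entropy(predict_proba(m, X), y)
        assert ce == pytest.approx(-m.log_likelihood / m.n_obs, abs=1e-10)

    def test_cross_entropy_perfect_predictions_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert cross_entropy(y, y) < 1e-10

    def test_aic_bic_formula(self):
        m = FittedLogisticModel(["a"], np.zeros(2), log_likelihood=-10.0,
                                n_obs=100, n_params=2)
        aic, bic = aic_bic(m)
        assert aic == pytest.approx(24.0)
        assert bic == pytest.approx(2 * math.log(100) + 20)

    def test_nested_models_likelihood_monotone(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 2))
        y = (rng.random(150) < 0.4).astype(float)
        small = fit_logistic(X[:, :1], y)
        big = fit_logistic(X, y)
        assert big.log_likelihood >= small.log_likelihood - 1e-8


class TestHosmerLemeshow:
    def test_perfect_agreement_zero_statistic(self):
        p = np.full(20, 0.5)
        y = np.tile([1.0, 0.0], 10)  # each bin of two holds one event
        stat, pval = hosmer_lemeshow(p, y)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == 1.0

    def test_miscalibration_grows_with_n(self):
        rng = np.random.default_rng(8)
        stats = []
        for n in (500, 4000):
            p_true = rng.uniform(0.05, 0.4, size=n)
            y = (rng.random(n) < p_true).astype(float)
            stat, _ = hosmer_lemeshow(np.clip(2 * p_true, 0, 0.95), y)
            stats.append(stat)
        assert stats[1] > stats[0]

    def test_null_rejection_rate_fitted_model(self):
        # under a correctly specified *fitted* model the test should reject
        # at roughly the nominal 5% level
        rng = np.random.default_rng(77)
        rejects = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=600)
            y = (rng.random(600) < 1 / (1 + np.exp(-(-1.2 + 0.9 * x)))).astype(float)
            m = fit_logistic(x[:, None], y)
            _, pval = hosmer_lemeshow(predict_proba(m, x[:, None]), y)
            rejects += pval < 0.05
        assert 0.01 <= rejects / n_sim <= 0.11


class TestSpearmanChi2:
    def test_spearman_examples(self):
        assert spearman_rcc([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman_rcc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = spearman_rcc(x, y)
        assert spearman_rcc(np.exp(x), y) == pytest.approx(base, abs=1e-12)

    def test_spearman_constant_raises(self):
        with pytest.raises(ValueError):
            spearman_rcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_chi_square_examples(self):
        assert chi_square_test([[10, 10], [10, 10]]) == pytest.approx(1.0)
        # Pearson statistic 60*(400-100)^2/30^4 = 20/3
        assert chi_square_test([[20, 10], [10, 20]]) == pytest.approx(0.00982, abs=1e-4)

    def test_chi_square_zero_margin_raises(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])
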