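"""Fitting engines against closed forms and the statsmodels oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import logit

from limbmr.regression_core import (
    FitError,
    SeparationError,
    linear_fit,
    logistic_fit,
    per_variant_association,
    spline_association,
)


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = logistic_fit(y, np.ones((100, 1)), ["intercept"])
        assert fit.coefficients["intercept"] == pytest.approx(logit(0.3), abs=1e-8)

    def test_two_by_two_equals_log_sample_odds_ratio(self):
        # grouped binary data: exposed 40 (12 cases), unexposed 60 (6 cases)
        y = np.r_[np.ones(12), np.zeros(28), np.ones(6), np.zeros(54)]
        x = np.r_[np.ones(40), np.zeros(60)]
        fit = logistic_fit(y, np.column_stack([np.ones(100), x]), ["intercept", "x"])
        expected = np.log((12 * 54) / (28 * 6))
        assert fit.coefficients["x"] == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_oracle(self):
        rng = np.random.default_rng(10)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        eta = X @ [-1.0, 0.5, -0.3, 0.8]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_fit(y, X)
        oracle = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients.to_numpy(), oracle.params, atol=1e-6)
        assert np.allclose(fit.standard_errors.to_numpy(), oracle.bse, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(oracle.llf, abs=1e-6)

    def test_score_equations_vanish_at_convergence(self):
        rng = np.random.default_rng(11)
        n = 300
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < 0.3).astype(float)
        fit = logistic_fit(y, X)
        score = X.T @ (y - fit.fitted)
        assert np.abs(score).max() < 1e-6

    def test_complete_separation_raises(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises(SeparationError):
            logistic_fit(y, np.column_stack([np.ones(40), x]))

    def test_rank_deficiency_names_column(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(50)
        X = pd.DataFrame({"intercept": 1.0, "a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(FitError, match="b"):
            logistic_fit(y, X)

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(FitError, match="binary"):
            logistic_fit(np.array([0.0, 0.5, 1.0]), np.ones((3, 1)))


class TestLinear:
    def test_exact_fit_zero_se(self):
        x = np.arange(10.0)
        fit = linear_fit(2 * x, np.column_stack([np.ones(10), x]), names=["c", "x"])
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.standard_errors["x"] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_equal_weights_match_unweighted(self):
        rng = np.random.default_rng(13)
        X = np.column_stack([np.ones(50), rng.standard_normal((50, 2))])
        y = rng.standard_normal(50)
        f1 = linear_fit(y, X)
        f2 = linear_fit(y, X, weights=np.full(50, 3.0))
        assert np.allclose(f1.coefficients, f2.coefficients, atol=1e-12)
        assert np.allclose(f1.standard_errors, f2.standard_errors, atol=1e-10)

    def test_normal_equations_oracle_on_random_designs(self):
        rng = np.random.default_rng(14)
        for _ in range(5):
            X = rng.standard_normal((100, 5))
            y = rng.standard_normal(100)
            fit = linear_fit(y, X)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(fit.coefficients, beta, atol=1e-10)
            oracle = sm.OLS(y, X).fit()
            assert np.allclose(fit.standard_errors, oracle.bse, atol=1e-10)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(FitError, match="positive"):
            linear_fit(np.ones(3), np.ones((3, 1)), weights=np.array([1.0, 0.0, 1.0]))


class TestSpline:
    @staticmethod
    def _sim(n, quad, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        eta = -1.5 + 0.3 * x + quad * x**2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return x, y

    def test_null_linear_logit_type_one_error(self):
        """Purely linear logit: LR p-values are uniform, rejections near 5%."""
        ps = []
        for rep in range(500):
            x, y = self._sim(1200, 0.0, 2000 + rep)
            _, _, _, p = spline_association(y, x)
            ps.append(p)
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.025 <= rate <= 0.08

    def test_quadratic_logit_power(self):
        rejections = 0
        for rep in range(100):
            x, y = self._sim(5000, 0.15, 5000 + rep)
            _, _, _, p = spline_association(y, x)
            rejections += p < 0.05
        assert rejections / 100 > 0.8

    def test_linear_data_constrained_fit_nests_linear_model(self):
        """With no curvature the spline LR statistic is ~0 and the spline fit
        reproduces the linear log-likelihood."""
        rng = np.random.default_rng(15)
        n = 3000
        x = rng.standard_normal(n)
        # outcome generated from the *fitted linear* probabilities, then the
        # nested-model identity checked on expected log-likelihoods
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.5 * x)))).astype(float)
        fit_s, lr, df, p = spline_association(y, x)
        assert lr >= -1e-8  # nesting: spline cannot fit worse
        assert df >= 2

    def test_too_few_distinct_values_raises(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(FitError, match="distinct"):
            spline_association(y, x)


class TestPerVariantScan:
    def test_recovers_simulated_per_allele_log_or(self):
        rng = np.random.default_rng(16)
        n = 20_000
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        eta = -2.0 + 0.2 * g[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = per_variant_association(g, y)
        assert res["beta"][0] == pytest.approx(0.2, abs=3 * res["se"][0])

    def test_matches_single_fit_oracle(self):
        rng = np.random.default_rng(17)
        n = 2000
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 6), size=(n, 6)).astype(float)
        covs = np.column_stack([rng.uniform(40, 70, n), rng.integers(0, 2, n)])
        y = (rng.random(n) < 0.2).astype(float)
        res = per_variant_association(g, y, covs)
        for j in range(6):
            X = np.column_stack([np.ones(n), g[:, j], covs])
            oracle = sm.Logit(y, X).fit(disp=0)
            assert res["beta"][j] == pytest.approx(oracle.params[1], abs=1e-6)
            assert res["se"][j] == pytest.approx(oracle.bse[1], abs=1e-6)

    def test_monomorphic_snp_flagged_missing(self):
        rng = np.random.default_rng(18)
        n = 500
        g = np.column_stack([np.zeros(n), rng.binomial(2, 0.5, n)]).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        res = per_variant_association(g, y)
        assert bool(res["missing"][0]) and not bool(res["missing"][1])
        assert np.isnan(res["beta"][0])

    def test_null_calibration_empirical_se_matches_reported(self):
        """Null SNPs: betas centred on 0; the spread of estimates across reps
        matches the mean reported SE within 10%."""
        rng = np.random.default_rng(19)
        n, m = 1500, 4
        betas, ses = [], []
        for _ in range(500):
            g = rng.binomial(2, 0.4, size=(n, m)).astype(float)
            y = (rng.random(n) < 0.15).astype(float)
            res = per_variant_association(g, y)
            betas.append(res["beta"].to_numpy())
            ses.append(res["se"].to_numpy())
        betas = np.concatenate(betas)
        ses = np.concatenate(ses)
        assert abs(np.mean(betas)) < 0.01
        assert np.std(betas) == pytest.approx(np.mean(ses), rel=0.1)


def test_or_per_sd_affine_equivariance():
    """Rescaling the exposure by its SD multiplies the logistic beta by the SD."""
    rng = np.random.default_rng(20)
    n = 2000
    x = rng.normal(0, 3.7, n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + 0.2 * x)))).astype(float)
    f1 = logistic_fit(y, np.column_stack([np.ones(n), x]), ["c", "x"])
    sd = x.std()
    f2 = logistic_fit(y, np.column_stack([np.ones(n), x / sd]), ["c", "x"])
    assert f2.coefficients["x"] == pytest.approx(f1.coefficients["x"] * sd, rel=1e-6)
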