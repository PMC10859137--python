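"""Summary-statistic estimators: closed forms, identities, simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbmr.two_sample_mr import (
    MetaInput,
    SummaryStats,
    SummaryStatsError,
    egger,
    ivw,
    make_summary_stats,
    meta_fixed,
    weighted_median,
)


def stats_from(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    m = bx.shape[0]
    return SummaryStats(
        pd.DataFrame(
            {
                "id": [f"rs{i}" for i in range(m)],
                "beta_x": bx,
                "se_x": np.full(m, 0.05) if sx is None else np.asarray(sx, float),
                "beta_y": by,
                "se_y": np.full(m, 0.1) if sy is None else np.asarray(sy, float),
            }
        )
    )


def sim_stats(rng, m, effect, pleiotropy_mean=0.0, pleiotropy_sd=0.0, n_invalid=0):
    """Summary statistics from the standard 2SMR generative model.

    Instrument precision mirrors large consortium GWAS: per-variant effects
    around 0.1-0.3 exposure SD with small standard errors, so per-variant
    Wald ratios are informative (ratio SE ~ 0.05)."""
    bx_true = rng.uniform(0.1, 0.3, m)
    sx = np.full(m, 0.004)
    sy = np.full(m, 0.01)
    alpha = np.zeros(m)
    if pleiotropy_sd or pleiotropy_mean:
        alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, m)
    if n_invalid:
        alpha[:n_invalid] = rng.normal(0.3, 0.05, n_invalid)
    bx = bx_true + rng.normal(0, 1, m) * sx
    by = effect * bx_true + alpha + rng.normal(0, 1, m) * sy
    return stats_from(bx, by, sx, sy)


class TestIVW:
    def test_single_variant_is_wald_ratio(self):
        est = ivw(stats_from([0.5], [0.1]))
        assert est.beta == pytest.approx(0.2, rel=1e-12)
        assert est.se == pytest.approx(0.1 / 0.5, rel=1e-12)

    def test_two_variant_closed_form(self):
        # w equal: slope = sum(bx*by)/sum(bx^2) = (0.2+0.4)/2 = 0.3
        est = ivw(stats_from([1.0, 1.0], [0.2, 0.4], sy=[0.1, 0.1]))
        assert est.beta == pytest.approx(0.3, rel=1e-12)

    def test_equals_weighted_mean_of_wald_ratios(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 20)
        by = rng.normal(0.3 * bx, 0.05)
        sy = rng.uniform(0.05, 0.2, 20)
        est = ivw(stats_from(bx, by, sy=sy))
        w = bx**2 / sy**2
        expected = np.sum(w * (by / bx)) / np.sum(w)
        assert est.beta == pytest.approx(expected, abs=1e-10)

    def test_unharmonized_rejected(self):
        s = stats_from([0.5], [0.1])
        s.harmonized = False
        with pytest.raises(SummaryStatsError, match="harmonized"):
            ivw(s)

    def test_recovery_simulation(self):
        rng = np.random.default_rng(1)
        est = np.array([ivw(sim_stats(rng, 50, 0.4)).beta for _ in range(500)])
        cover = np.array(
            [
                e.ci_low <= 0.4 <= e.ci_high
                for e in (ivw(sim_stats(rng, 50, 0.4)) for _ in range(500))
            ]
        )
        # small O(1/m) weak-instrument ratio bias is expected; 0.01 covers it
        assert est.mean() == pytest.approx(0.4, abs=0.01)
        assert 0.92 <= cover.mean() <= 0.97


class TestEgger:
    def test_exact_line_through_two_points(self):
        est = egger(stats_from([1.0, 2.0], [0.3, 0.5]), min_variants=2)
        assert est.beta == pytest.approx(0.2, abs=1e-10)
        assert est.diagnostics["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_too_few_variants_rejected(self):
        with pytest.raises(SummaryStatsError, match="at least 3"):
            egger(stats_from([1.0, 2.0], [0.3, 0.5]))

    def test_negative_beta_x_reorientation_invariance(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.4, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        flip = np.ones(10)
        flip[::2] = -1
        e1 = egger(stats_from(bx, by))
        e2 = egger(stats_from(bx * flip, by * flip))
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
        assert e1.diagnostics["intercept"] == pytest.approx(
            e2.diagnostics["intercept"], abs=1e-12
        )

    def test_directional_pleiotropy_intercept_and_slopes(self):
        """alpha ~ N(0.05, tau): the Egger intercept centres on 0.05 and the
        Egger slope stays unbiased while IVW is biased upward (InSIDE)."""
        rng = np.random.default_rng(3)
        intercepts, egger_b, ivw_b = [], [], []
        for _ in range(500):
            s = sim_stats(rng, 50, 0.4, pleiotropy_mean=0.05, pleiotropy_sd=0.02)
            e = egger(s)
            intercepts.append(e.diagnostics["intercept"])
            egger_b.append(e.beta)
            ivw_b.append(ivw(s).beta)
        sem = np.std(intercepts) / np.sqrt(500)
        assert np.mean(intercepts) == pytest.approx(0.05, abs=4 * sem)
        assert abs(np.mean(egger_b) - 0.4) < 0.05
        assert np.mean(ivw_b) - 0.4 > 0.1  # clearly biased

    def test_balanced_pleiotropy_intercept_near_zero(self):
        rng = np.random.default_rng(4)
        intercepts = [
            egger(sim_stats(rng, 50, 0.4, pleiotropy_sd=0.05)).diagnostics["intercept"]
            for _ in range(300)
        ]
        sem = np.std(intercepts) / np.sqrt(300)
        assert np.mean(intercepts) == pytest.approx(0.0, abs=4 * sem)

    def test_agrees_with_ivw_without_pleiotropy(self):
        rng = np.random.default_rng(5)
        diff = [
            egger(s).beta - ivw(s).beta
            for s in (sim_stats(rng, 50, 0.4) for _ in range(200))
        ]
        assert abs(np.mean(diff)) < 0.02


class TestWeightedMedian:
    def test_equal_weight_median_of_ratios(self):
        # negligible se_x so the delta-method weights are exactly equal
        est = weighted_median(
            stats_from([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], sx=[1e-12] * 3),
            n_boot=50, seed=1,
        )
        assert est.beta == pytest.approx(0.2, abs=1e-10)

    def test_breakdown_resistance_with_invalid_instruments(self):
        """10 valid instruments (effect 0.3) + 4 strongly pleiotropic: the
        weighted median stays near 0.3 while IVW is biased."""
        rng = np.random.default_rng(6)
        wm, iv = [], []
        for _ in range(500):
            s = sim_stats(rng, 14, 0.3, n_invalid=4)
            wm.append(weighted_median(s, n_boot=20, seed=0).beta)
            iv.append(ivw(s).beta)
        assert abs(np.mean(wm) - 0.3) < 0.05
        assert np.mean(iv) - 0.3 > 0.2

    def test_penalization_noop_when_homogeneous(self):
        rng = np.random.default_rng(7)
        s = sim_stats(rng, 20, 0.4)
        plain = weighted_median(s, penalized=False, n_boot=10, seed=2)
        pen = weighted_median(s, penalized=True, n_boot=10, seed=2)
        # with tight instruments all Q_j are below the 5% chi-square quantile
        assert pen.beta == pytest.approx(plain.beta, abs=1e-6)

    def test_penalized_downweights_outlier(self):
        bx = np.full(11, 0.2)
        by = 0.3 * 0.2 * np.ones(11)
        by[0] = 0.5  # gross outlier
        s = stats_from(bx, by, sx=np.full(11, 1e-4), sy=np.full(11, 0.005))
        plain = weighted_median(s, penalized=False, n_boot=10, seed=3)
        pen = weighted_median(s, penalized=True, n_boot=10, seed=3)
        assert abs(pen.beta - 0.3) <= abs(plain.beta - 0.3) + 1e-12

    def test_zero_beta_x_excluded(self):
        s = stats_from([0.0, 1.0, 1.0, 1.0], [0.1, 0.1, 0.2, 0.3])
        est = weighted_median(s, n_boot=10, seed=4)
        assert est.n_instruments == 3
        assert est.diagnostics["excluded_zero_beta_x"] == ["rs0"]


class TestMeta:
    def test_closed_form(self):
        pooled, se, _ = meta_fixed(
            [MetaInput("a", 0.1, 0.1), MetaInput("b", 0.3, 0.1)]
        )
        assert pooled == pytest.approx(0.2, rel=1e-12)
        assert se == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_identical_cohorts_shrink_se_by_sqrt2(self):
        pooled, se, _ = meta_fixed([MetaInput("a", 0.25, 0.2), MetaInput("b", 0.25, 0.2)])
        assert pooled == pytest.approx(0.25)
        assert se == pytest.approx(0.2 / np.sqrt(2), rel=1e-12)

    def test_huge_se_cohort_is_ignored(self):
        pooled, se, _ = meta_fixed([MetaInput("a", 0.3, 0.05), MetaInput("b", 5.0, 100.0)])
        assert pooled == pytest.approx(0.3, abs=1e-4)

    def test_single_cohort_passthrough_with_warning(self):
        pooled, se, diag = meta_fixed([MetaInput("a", 0.3, 0.05)])
        assert (pooled, se) == (0.3, 0.05)
        assert "warning" in diag

    def test_order_invariance_and_se_bound(self):
        rng = np.random.default_rng(8)
        inputs = [MetaInput(str(i), rng.normal(), rng.uniform(0.1, 1)) for i in range(5)]
        p1, s1, _ = meta_fixed(inputs)
        p2, s2, _ = meta_fixed(inputs[::-1])
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert s1 <= min(c.se for c in inputs)


class TestInvariances:
    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.5, 3.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance(self, c, seed):
        """Multiplying every beta_x by c divides every estimator by c."""
        rng = np.random.default_rng(seed)
        s = sim_stats(rng, 10, 0.4)
        t2 = s.table.copy()
        t2["beta_x"] *= c
        t2["se_x"] *= c
        s2 = SummaryStats(t2)
        assert ivw(s2).beta == pytest.approx(ivw(s).beta / c, rel=1e-9)
        assert weighted_median(s2, n_boot=5, seed=0).beta == pytest.approx(
            weighted_median(s, n_boot=5, seed=0).beta / c, rel=1e-9
        )

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_sign_symmetry(self, seed):
        """Negating all beta_y negates every estimator."""
        rng = np.random.default_rng(seed)
        s = sim_stats(rng, 10, 0.4)
        t2 = s.table.copy()
        t2["beta_y"] *= -1
        s2 = SummaryStats(t2)
        assert ivw(s2).beta == pytest.approx(-ivw(s).beta, rel=1e-9)
        assert egger(s2).beta == pytest.approx(-egger(s).beta, rel=1e-9)
        assert weighted_median(s2, n_boot=5, seed=0).beta == pytest.approx(
            -weighted_median(s, n_boot=5, seed=0).beta, rel=1e-6
        )


class TestHarmonizedPairing:
    def test_outcome_beta_flipped_to_exposure_effect_allele(self):
        exp = pd.DataFrame(
            {
                "id": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
                "beta": [0.2], "se": [0.02],
            }
        )
        out = pd.DataFrame(
            {
                "id": ["rs1"], "effect_allele": ["G"], "other_allele": ["A"],
                "beta": [0.1], "se": [0.05],
            }
        )
        stats, excl = make_summary_stats(exp, out)
        assert stats.table["beta_y"][0] == pytest.approx(-0.1)
        assert excl == []

    def test_unmatched_variant_excluded(self):
        exp = pd.DataFrame(
            {
                "id": ["rs1", "rs2"], "effect_allele": ["A", "C"],
                "other_allele": ["G", "T"], "beta": [0.2, 0.1], "se": [0.02, 0.02],
            }
        )
        out = exp.iloc[:1].assign(beta=0.05, se=0.03)
        stats, excl = make_summary_stats(exp, out)
        assert len(stats) == 1
        assert ("rs2", "absent from outcome statistics") in excl
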