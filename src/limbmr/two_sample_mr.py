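"""Summary-statistic (two-sample) MR estimators and cross-cohort meta-analysis.

All estimators act on per-variant harmonized pairs of genotype-exposure
(``beta_x``, ``se_x``) and genotype-outcome (``beta_y``, ``se_y``) effects:

* IVW — inverse-variance-weighted regression of ``beta_y`` on ``beta_x``
  through the origin; standard error under multiplicative random effects
  with the residual dispersion floored at 1, so the fixed-effect answer is
  the lower bound.  Cochran's Q measures heterogeneity.
* MR-Egger — the same regression with a free intercept (variants re-oriented
  to non-negative ``beta_x``); the intercept estimates average directional
  pleiotropy and the slope is consistent under InSIDE.
* Weighted median (and its penalized variant) — the 50% point of the
  inverse-variance-weight CDF over sorted per-variant Wald ratios;
  consistent while at least half the weight comes from valid instruments.
* Fixed-effect meta-analysis pools per-cohort betas by inverse variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .one_sample_mr import MREstimate, Z95

__all__ = [
    "SummaryStats",
    "MetaInput",
    "SummaryStatsError",
    "ivw",
    "egger",
    "weighted_median",
    "meta_fixed",
    "make_summary_stats",
]


class SummaryStatsError(ValueError):
    """Unusable summary statistics."""


@dataclass
class SummaryStats:
    """Harmonized per-variant effect pairs for two-sample MR."""

    table: pd.DataFrame  # id, beta_x, se_x, beta_y, se_y
    harmonized: bool = True

    def __post_init__(self) -> None:
        required = {"id", "beta_x", "se_x", "beta_y", "se_y"}
        missing = required - set(self.table.columns)
        if missing:
            raise SummaryStatsError(f"summary stats missing column(s) {sorted(missing)}")
        if self.table["id"].duplicated().any():
            dups = self.table["id"][self.table["id"].duplicated()].tolist()
            raise SummaryStatsError(f"variant(s) appear twice: {dups}")
        if (self.table[["se_x", "se_y"]] <= 0).any().any():
            raise SummaryStatsError("standard errors must be positive")

    def __len__(self) -> int:
        return len(self.table)

    def _require_harmonized(self, method: str) -> None:
        if not self.harmonized:
            raise SummaryStatsError(
                f"{method} requires allele-harmonized summary statistics"
            )


@dataclass
class MetaInput:
    label: str
    beta: float
    se: float


def _estimate(method: str, beta: float, se: float, n: int, diagnostics: dict) -> MREstimate:
    z = beta / se if se > 0 else np.inf
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        p=float(2 * norm.sf(abs(z))),
        n_instruments=n,
        scale="per exposure unit",
        diagnostics=diagnostics,
    )


def ivw(stats: SummaryStats) -> MREstimate:
    """Inverse-variance-weighted estimate (weighted regression through origin)."""
    stats._require_harmonized("IVW")
    t = stats.table
    if len(t) < 1:
        raise SummaryStatsError("IVW needs at least one variant")
    bx = t["beta_x"].to_numpy(float)
    by = t["beta_y"].to_numpy(float)
    w = 1.0 / t["se_y"].to_numpy(float) ** 2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise SummaryStatsError("all exposure effects are zero")
    slope = float(np.sum(w * bx * by)) / denom
    q = float(np.sum(w * (by - slope * bx) ** 2))
    m = len(t)
    # multiplicative random effects: residual dispersion floored at 1
    disp = max(q / (m - 1), 1.0) if m > 1 else 1.0
    se = float(np.sqrt(disp / denom))
    q_p = float(chi2.sf(q, m - 1)) if m > 1 else float("nan")
    return _estimate(
        "IVW", slope, se, m, {"cochran_q": q, "q_df": m - 1, "q_p": q_p, "dispersion": disp}
    )


def egger(stats: SummaryStats, min_variants: int = 3) -> MREstimate:
    """MR-Egger: weighted regression with a free pleiotropy intercept.

    Variants are re-oriented so every ``beta_x`` is non-negative (flipping
    ``beta_y`` along with it), which the intercept needs to be
    interpretable.  The returned estimate is the slope; the intercept, its
    SE and its Wald p live in the diagnostics.
    """
    stats._require_harmonized("MR-Egger")
    t = stats.table
    if len(t) < min_variants:
        raise SummaryStatsError(
            f"MR-Egger needs at least {min_variants} variants (got {len(t)})"
        )
    bx = t["beta_x"].to_numpy(float).copy()
    by = t["beta_y"].to_numpy(float).copy()
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / t["se_y"].to_numpy(float) ** 2
    X = np.column_stack([np.ones(len(bx)), bx])
    xtwx = (X * w[:, None]).T @ X
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    m = len(bx)
    q = float(np.sum(w * resid**2))
    disp = max(q / (m - 2), 1.0) if m > 2 else 1.0
    cov = disp * np.linalg.inv(xtwx)
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    z_int = coef[0] / se_int if se_int > 0 else np.inf
    return _estimate(
        "MR-Egger",
        coef[1],
        se_slope,
        m,
        {
            "intercept": float(coef[0]),
            "intercept_se": se_int,
            "intercept_p": float(2 * norm.sf(abs(z_int))),
            "dispersion": disp,
        },
    )


def _median_of_weight_cdf(ratios: np.ndarray, weights: np.ndarray) -> float:
    """50% point of the standardized weight CDF over sorted ratios,
    linearly interpolated (the weighted-median rule of Bowden et al.)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = np.cumsum(w) - 0.5 * w
    s = s / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    stats: SummaryStats,
    penalized: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    min_variants: int = 3,
) -> MREstimate:
    """(Penalized) weighted-median estimate with parametric-bootstrap SE.

    Per-variant Wald ratios are weighted by the inverse of their
    delta-method variance.  The penalized form down-weights heterogeneous
    variants by ``min(1, q_5% / Q_j)`` where ``Q_j`` is the variant's
    contribution to Cochran's Q about the unpenalized estimate and ``q_5%``
    the upper 5% chi-square(1) quantile.  Variants with ``beta_x = 0`` are
    excluded (infinite ratio) and listed in the diagnostics.
    """
    stats._require_harmonized("weighted median")
    t = stats.table
    keep = t["beta_x"].to_numpy(float) != 0.0
    dropped = t.loc[~keep, "id"].tolist()
    t = t.loc[keep]
    if len(t) < min_variants:
        raise SummaryStatsError(
            f"weighted median needs at least {min_variants} usable variants (got {len(t)})"
        )
    bx = t["beta_x"].to_numpy(float)
    by = t["beta_y"].to_numpy(float)
    sx = t["se_x"].to_numpy(float)
    sy = t["se_y"].to_numpy(float)

    def point_estimate(bx, by):
        ratios = by / bx
        var = sy**2 / bx**2 + (by**2 * sx**2) / bx**4
        w = 1.0 / var
        est = _median_of_weight_cdf(ratios, w)
        if penalized:
            qj = w * (ratios - est) ** 2
            penalty = np.minimum(1.0, chi2.ppf(0.95, 1) / np.maximum(qj, 1e-300))
            est = _median_of_weight_cdf(ratios, w * penalty)
        return est

    est = point_estimate(bx, by)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = point_estimate(
            bx + sx * rng.standard_normal(bx.shape),
            by + sy * rng.standard_normal(by.shape),
        )
    se = float(boot.std(ddof=1))
    method = "penalized weighted median" if penalized else "weighted median"
    return _estimate(
        method, est, se, len(t), {"excluded_zero_beta_x": dropped, "n_boot": n_boot}
    )


def meta_fixed(inputs: list[MetaInput]) -> tuple[float, float, dict]:
    """Fixed-effect inverse-variance pooling of per-cohort estimates.

    Returns ``(pooled_beta, pooled_se, diagnostics)``; diagnostics carry
    Cochran's Q, its p-value and I^2.  A single cohort passes through with
    a warning flag in the diagnostics.
    """
    if len(inputs) == 0:
        raise SummaryStatsError("meta-analysis needs at least one cohort")
    betas = np.array([c.beta for c in inputs], dtype=float)
    ses = np.array([c.se for c in inputs], dtype=float)
    if (ses <= 0).any():
        raise SummaryStatsError("cohort standard errors must be positive")
    if len(inputs) == 1:
        return float(betas[0]), float(ses[0]), {"warning": "single cohort: pass-through"}
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(inputs) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return pooled, pooled_se, {
        "cochran_q": q,
        "q_df": df,
        "q_p": float(chi2.sf(q, df)),
        "i_squared": i2,
    }


def make_summary_stats(
    exposure_side: pd.DataFrame,
    outcome_side: pd.DataFrame,
) -> tuple[SummaryStats, list[tuple[str, str]]]:
    """Pair exposure-side and outcome-side per-variant effects, harmonizing alleles.

    ``exposure_side`` needs id/effect_allele/other_allele/beta/se (eaf
    optional); ``outcome_side`` needs id/effect_allele/other_allele/beta/se
    (eaf optional).  Outcome betas are aligned to the exposure effect
    allele; unresolvable variants are excluded with reasons.
    """
    from .instruments import align_alleles

    exp = exposure_side.set_index("id")
    out = outcome_side.set_index("id")
    rows = []
    exclusions: list[tuple[str, str]] = []
    for vid in exp.index:
        if vid not in out.index:
            exclusions.append((str(vid), "absent from outcome statistics"))
            continue
        e, o = exp.loc[vid], out.loc[vid]
        sign, reason = align_alleles(
            str(e["effect_allele"]),
            str(e["other_allele"]),
            str(o["effect_allele"]),
            str(o["other_allele"]),
            eaf_effect=float(e["eaf"]) if "eaf" in e.index and pd.notna(e["eaf"]) else None,
            eaf_counted=float(o["eaf"]) if "eaf" in o.index and pd.notna(o["eaf"]) else None,
        )
        if sign == 0.0:
            exclusions.append((str(vid), reason))
            continue
        if not (np.isfinite(o["beta"]) and np.isfinite(o["se"]) and o["se"] > 0):
            exclusions.append((str(vid), "missing outcome estimate"))
            continue
        rows.append(
            {
                "id": vid,
                "beta_x": float(e["beta"]),
                "se_x": float(e["se"]),
                "beta_y": sign * float(o["beta"]),
                "se_y": float(o["se"]),
            }
        )
    if not rows:
        raise SummaryStatsError("no variants could be harmonized across the two samples")
    return SummaryStats(pd.DataFrame(rows)), exclusions
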