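"""One-sample Mendelian randomization by two-stage regression.

Stage one regresses the exposure on a normalized genetic risk score,
adjusted for the first five genetic principal components; stage two
regresses the outcome on the normalized predicted exposure, adjusted for
the first-stage residuals (residual inclusion), age and sex.  The default
second stage is linear — a linear-probability causal coefficient converted
to an odds ratio through the baseline prevalence — mirroring the two-stage
procedure biobank analyses report; a logistic residual-inclusion (2SRI)
second stage is provided and is the estimator of choice when the outcome is
rare or the effect is not small, because it works on the log-odds scale
directly and needs no risk-difference conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .instruments import (
    GeneticRiskScore,
    InstrumentError,
    compute_grs,
    harmonize,
    instrument_f_statistic,
)
from .regression_core import FitError, linear_fit, logistic_fit

__all__ = [
    "MREstimate",
    "FirstStage",
    "first_stage",
    "second_stage",
    "rescale_estimate",
    "run_one_sample_mr",
]

Z95 = norm.ppf(0.975)


@dataclass
class MREstimate:
    """Causal-effect estimate on the log-odds (or linear working) scale.

    ``beta``, ``se`` and the 95% CI live on the working (log-OR) scale;
    ``or_``/``or_ci_low``/``or_ci_high`` exponentiate them.  ``scale``
    documents the exposure unit the effect refers to (e.g. ``"per SD"``).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    scale: str = "per SD"
    diagnostics: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))


@dataclass
class FirstStage:
    predicted: np.ndarray  # fitted exposure values (exposure units)
    predicted_norm: np.ndarray  # z-scored fitted values
    predicted_sd: float  # SD of fitted values, in exposure units
    residuals: np.ndarray
    f_statistic: float
    r_squared: float  # incremental R^2 of the GRS over the PCs


def first_stage(
    exposure: np.ndarray, grs: GeneticRiskScore, pcs: np.ndarray
) -> FirstStage:
    """Linear regression of exposure on normalized GRS + 5 PCs."""
    x = np.asarray(grs.values, dtype=float)
    if x.std() == 0:
        raise InstrumentError("constant GRS cannot instrument the exposure")
    pcs = np.asarray(pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[1] != 5:
        raise FitError(f"expected 5 principal components, got shape {pcs.shape}")
    n = x.shape[0]
    design = np.column_stack([np.ones(n), x, pcs])
    names = ["intercept", "grs", "pc1", "pc2", "pc3", "pc4", "pc5"]
    fit = linear_fit(exposure, design, names=names)
    predicted = fit.fitted
    sd = predicted.std()
    if sd == 0:
        raise InstrumentError("first-stage predictions are constant")
    f, r2 = instrument_f_statistic(x, np.asarray(exposure, dtype=float), pcs)
    return FirstStage(
        predicted=predicted,
        predicted_norm=(predicted - predicted.mean()) / sd,
        predicted_sd=float(sd),
        residuals=fit.residuals,
        f_statistic=f,
        r_squared=r2,
    )


def second_stage(
    outcome: np.ndarray,
    predicted_norm: np.ndarray,
    residuals: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    mode: str = "linear",
):
    """Outcome on normalized predicted exposure + residuals + age + sex.

    ``mode="linear"`` returns a risk-difference coefficient per 1 SD of the
    predicted exposure; ``mode="logistic-2sri"`` returns a log-odds
    coefficient on the same scale.  Returns ``(beta, se, fit)``.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise FitError("outcome must be binary 0/1 for the MR second stage")
    n = y.shape[0]
    design = np.column_stack([np.ones(n), predicted_norm, residuals, age, sex])
    names = ["intercept", "predicted", "residuals", "age", "sex"]
    if mode == "linear":
        fit = linear_fit(y, design, names=names)
    elif mode == "logistic-2sri":
        fit = logistic_fit(y, design, names=names)
    else:
        raise FitError(f"unknown second-stage mode {mode!r}")
    return float(fit.coefficients["predicted"]), float(fit.standard_errors["predicted"]), fit


def rescale_estimate(
    beta: float,
    se: float,
    mode: str,
    exposure_sd: float,
    predicted_sd: float,
    baseline_prevalence: float,
    target_unit="SD",
    diagnostics: dict | None = None,
    n_instruments: int = 0,
) -> MREstimate:
    """Convert a raw second-stage coefficient to an OR on a chosen scale.

    The raw coefficient is per 1 SD of the *predicted* exposure; dividing
    by ``predicted_sd`` gives a per-exposure-unit effect, which is then
    scaled to ``target_unit`` (a number of exposure units, or ``"SD"`` for
    ``exposure_sd`` units).  In logistic-2SRI mode that unit-scaled effect
    is already a log-OR.  In linear mode it is a risk difference delta,
    converted through the baseline odds:
    ``OR = ((p0+delta)/(1-p0-delta)) / (p0/(1-p0))``;
    CI endpoints go through the identical map.
    """
    unit = float(exposure_sd) if isinstance(target_unit, str) else float(target_unit)
    scale_label = "per SD" if isinstance(target_unit, str) else f"per {target_unit} units"
    factor = unit / predicted_sd
    b_unit = beta * factor
    lo_unit = (beta - Z95 * se) * factor
    hi_unit = (beta + Z95 * se) * factor
    if mode == "logistic-2sri":
        log_or, lo, hi = b_unit, lo_unit, hi_unit
        se_out = se * abs(factor)
    elif mode == "linear":
        p0 = float(baseline_prevalence)
        if not 0 < p0 < 1:
            raise FitError("baseline prevalence must lie in (0,1)")

        def to_log_or(delta: float) -> float:
            p1 = p0 + delta
            if not 0 < p1 < 1:
                raise FitError(
                    f"risk difference {delta:.4g} pushes prevalence outside (0,1); "
                    "use the logistic-2sri mode"
                )
            return float(np.log((p1 / (1 - p1)) / (p0 / (1 - p0))))

        log_or = to_log_or(b_unit)
        lo, hi = to_log_or(lo_unit), to_log_or(hi_unit)
        se_out = (hi - lo) / (2 * Z95) if hi > lo else 0.0
    else:
        raise FitError(f"unknown mode {mode!r}")
    z = beta / se if se > 0 else np.inf
    p = float(2 * norm.sf(abs(z)))
    diag = dict(diagnostics or {})
    diag.update({"mode": mode, "predicted_sd": predicted_sd, "exposure_sd": exposure_sd,
                 "baseline_prevalence": baseline_prevalence})
    return MREstimate(
        method="one-sample two-stage",
        beta=log_or,
        se=se_out,
        ci_low=lo,
        ci_high=hi,
        p=p,
        n_instruments=n_instruments,
        scale=scale_label,
        diagnostics=diag,
    )


def run_one_sample_mr(
    cohort,
    instrument_table,
    case_status,
    mode: str = "linear",
    target_unit="SD",
) -> MREstimate:
    """Full chain: harmonize -> GRS -> first stage -> second stage -> rescale.

    ``case_status`` may be a CaseStatus or a plain binary vector aligned
    with the cohort.  The baseline prevalence used by the linear-mode OR
    conversion is the sample prevalence.
    """
    status = getattr(case_status, "status", case_status)
    weights, exclusions = harmonize(instrument_table, cohort.coding)
    grs = compute_grs(cohort.genotypes, weights, exclusions)
    fs = first_stage(cohort.exposure, grs, cohort.pcs)
    beta, se, _ = second_stage(
        status, fs.predicted_norm, fs.residuals, cohort.age, cohort.sex, mode=mode
    )
    est = rescale_estimate(
        beta,
        se,
        mode,
        exposure_sd=float(np.asarray(cohort.exposure).std()),
        predicted_sd=fs.predicted_sd,
        baseline_prevalence=float(np.mean(status)),
        target_unit=target_unit,
        diagnostics={
            "F": fs.f_statistic,
            "first_stage_r2": fs.r_squared,
            "n_excluded": len(exclusions),
        },
        n_instruments=grs.n_variants_used,
    )
    return est
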