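"""Shared fitting engines: logistic ML, (weighted) least squares, splines,
and a batched per-variant association scan.

The logistic fitter is a plain iteratively-reweighted-least-squares (IRLS)
Newton scheme with Wald standard errors from the observed information; it
refuses to report estimates under complete separation or rank deficiency.
The per-variant scan runs the same IRLS jointly over all variants (the
design matrices differ only in the dosage column), which keeps simulation
studies with tens of thousands of fits tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

__all__ = [
    "FitResult",
    "FitError",
    "SeparationError",
    "logistic_fit",
    "linear_fit",
    "spline_association",
    "per_variant_association",
]

SCORE_TOL = 1e-8
MAX_ITER = 100


class FitError(ValueError):
    """Design or response unusable for the requested fit."""


class SeparationError(FitError):
    """Complete/quasi-complete separation: the MLE does not exist."""


@dataclass
class FitResult:
    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: np.ndarray
    n: int
    converged: bool
    log_likelihood: float | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def wald_p(self, name: str) -> float:
        from scipy.stats import norm

        z = self.coefficients[name] / self.standard_errors[name]
        return float(2 * norm.sf(abs(z)))


def _as_design(X, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 0.0
    bad = np.where(diag <= 1e-10 * max(scale, 1.0))[0]
    if bad.size:
        raise FitError(
            f"design matrix is rank deficient; collinear column(s): "
            f"{[names[j] for j in bad]}"
        )


def logistic_fit(y, X, names=None) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Converges on the score norm (max |X'(y-p)| < 1e-8).  Raises
    :class:`SeparationError` for degenerate responses or diverging
    coefficients, and :class:`FitError` (naming columns) for rank-deficient
    designs.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise FitError("outcome must be binary 0/1")
    X, names = _as_design(X, names)
    n = X.shape[0]
    if y.shape[0] != n:
        raise FitError(f"y has length {y.shape[0]}, design has {n} rows")
    if y.min() == y.max():
        raise SeparationError(
            f"outcome is constant (all {int(y[0])}); logistic MLE does not exist"
        )
    _check_rank(X, names)

    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        if np.abs(eta).max() > 40:
            raise SeparationError(
                "diverging linear predictor: complete or quasi-complete separation"
            )
        p = expit(eta)
        w = p * (1 - p)
        score = X.T @ (y - p)
        if np.abs(score).max() < SCORE_TOL:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # step-halving keeps IRLS stable on poorly scaled designs
        step = 1.0
        ll0 = _loglik(y, eta)
        for _ in range(20):
            cand = beta + step * delta
            if _loglik(y, X @ cand) >= ll0 - 1e-12:
                break
            step /= 2
        beta = beta + step * delta
    if not converged:
        raise SeparationError("IRLS failed to converge (possible separation)")
    if np.abs(X @ beta).max() > 20:
        # score can vanish numerically while the MLE diverges
        raise SeparationError(
            "fitted probabilities reach 0/1: complete or quasi-complete separation"
        )
    p = expit(X @ beta)
    w = p * (1 - p)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    return FitResult(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        covariance=cov,
        n=n,
        converged=True,
        log_likelihood=_loglik(y, X @ beta),
        fitted=p,
        residuals=y - p,
    )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood in terms of the linear predictor
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def linear_fit(y, X, weights=None, names=None, scale: str = "residual") -> FitResult:
    """(Weighted) least squares.

    ``scale`` sets the dispersion used for the covariance: ``"residual"``
    (the usual estimate), ``"unit"`` (covariance = (X'WX)^-1, for
    fixed-weight inverse-variance problems), or ``"floored"`` (residual
    dispersion floored at 1 — multiplicative random effects with the
    fixed-effect answer as the lower bound).
    """
    y = np.asarray(y, dtype=float)
    X, names = _as_design(X, names)
    n, k = X.shape
    if y.shape[0] != n:
        raise FitError(f"y has length {y.shape[0]}, design has {n} rows")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise FitError("weights must be positive")
    _check_rank(X * np.sqrt(w)[:, None], names)

    xtwx = (X * w[:, None]).T @ X
    beta = np.linalg.solve(xtwx, (X * w[:, None]).T @ y)
    resid = y - X @ beta
    xtwx_inv = np.linalg.inv(xtwx)
    dof = max(n - k, 1)
    s2 = float((w * resid**2).sum() / dof)
    if scale == "residual":
        disp = s2
    elif scale == "unit":
        disp = 1.0
    elif scale == "floored":
        disp = max(s2, 1.0)
    else:
        raise FitError(f"unknown scale {scale!r}")
    cov = disp * xtwx_inv
    se = np.sqrt(np.diag(cov))
    return FitResult(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        covariance=cov,
        n=n,
        converged=True,
        fitted=X @ beta,
        residuals=resid,
    )


def _natural_spline_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic regression-spline design (patsy ``cr``).

    The outer knots become the spline's natural-linearity bounds and the
    remaining knots its interior knots; the returned basis (one column per
    knot) spans the full natural cubic spline space on ``knots``, which
    contains every constant and linear function — so the linear logistic
    model is strictly nested in the spline model.
    """
    from patsy import dmatrix

    interior = knots[1:-1]
    return np.asarray(
        dmatrix(
            "cr(x, knots=interior, lower_bound=lb, upper_bound=ub) - 1",
            {"x": x, "interior": interior, "lb": knots[0], "ub": knots[-1]},
        )
    )


def spline_association(y, exposure, covariates=None, n_knots: int = 5):
    """Logistic spline fit with a likelihood-ratio test against linearity.

    Natural cubic spline with ``n_knots`` knots placed at the exposure
    quantiles (0.05, 0.275, 0.5, 0.725, 0.95); the non-linearity test is the
    LR chi-square of the spline model against the model with a single
    linear exposure term, both adjusted for the same covariates.

    Returns ``(spline_fit, lr_stat, df, p_value)``.
    """
    x = np.asarray(exposure, dtype=float)
    n = x.shape[0]
    quantiles = np.linspace(0.05, 0.95, n_knots)
    knots = np.quantile(x, quantiles)
    if np.unique(knots).size < n_knots:
        raise FitError(
            f"fewer than {n_knots} distinct exposure quantiles; spline fit impossible"
        )
    if covariates is None:
        covariates = np.empty((n, 0))
    C, cov_names = _as_design(covariates) if np.size(covariates) else (np.empty((n, 0)), [])
    basis = _natural_spline_design(x, knots)  # spans constant + linear + curvature
    X_spline = np.column_stack([basis, C])
    spline_names = [f"spline{j}" for j in range(basis.shape[1])] + [
        f"cov{j}" for j in range(C.shape[1])
    ]
    X_linear = np.column_stack([np.ones(n), x, C])
    linear_names = ["intercept", "exposure"] + [f"cov{j}" for j in range(C.shape[1])]
    fit_s = logistic_fit(y, X_spline, spline_names)
    fit_l = logistic_fit(y, X_linear, linear_names)
    lr = 2.0 * (fit_s.log_likelihood - fit_l.log_likelihood)
    lr = max(lr, 0.0)
    df = X_spline.shape[1] - X_linear.shape[1]
    p = float(chi2.sf(lr, df))
    return fit_s, float(lr), int(df), p


def per_variant_association(
    genotypes: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_ids=None,
) -> pd.DataFrame:
    """Per-SNP covariate-adjusted logistic associations, fitted in a batch.

    For each variant: logistic regression of the binary outcome on dosage
    plus the shared covariates; beta is the log-odds per counted allele.
    Monomorphic variants (or non-converging fits) are flagged with NaN
    beta/se rather than zero.  Missing dosages are mean-imputed per SNP.
    """
    y = np.asarray(y, dtype=float)
    G = np.array(genotypes, dtype=float)
    n, m = G.shape
    if np.isnan(G).any():
        col_mean = np.nanmean(G, axis=0)
        idx = np.where(np.isnan(G))
        G[idx] = col_mean[idx[1]]
    if covariates is None:
        covariates = np.empty((n, 0))
    C, _ = _as_design(covariates) if np.size(covariates) else (np.empty((n, 0)), [])
    k = 2 + C.shape[1]
    shared = np.column_stack([np.ones(n), C])

    poly = G.std(axis=0) > 0
    betas = np.full((m, k), np.nan)
    ok = poly.copy()
    active = np.where(poly)[0]
    # batched IRLS: one Newton system per variant per iteration
    B = np.zeros((active.size, k))
    X = np.empty((active.size, n, k))
    X[:, :, 0] = 1.0
    X[:, :, 1] = G[:, active].T
    if C.shape[1]:
        X[:, :, 2:] = shared[None, :, 1:]
    alive = np.ones(active.size, dtype=bool)
    for _ in range(MAX_ITER):
        eta = np.einsum("vnk,vk->vn", X, B)
        p = expit(eta)
        w = p * (1 - p)
        score = np.einsum("vnk,vn->vk", X, y[None, :] - p)
        done = np.abs(score).max(axis=1) < SCORE_TOL
        diverged = np.abs(eta).max(axis=1) > 40
        alive &= ~done & ~diverged
        if not alive.any():
            break
        idx = np.where(alive)[0]
        info = np.einsum("vnk,vn,vnl->vkl", X[idx], w[idx], X[idx])
        try:
            delta = np.linalg.solve(info, score[idx][:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            # fall back to per-variant solves, dropping singular ones
            delta = np.zeros_like(score[idx])
            for t, v in enumerate(idx):
                try:
                    delta[t] = np.linalg.solve(info[t], score[v])
                except np.linalg.LinAlgError:
                    alive[v] = False
        B[idx] += delta
    eta = np.einsum("vnk,vk->vn", X, B)
    p = expit(eta)
    w = p * (1 - p)
    score = np.einsum("vnk,vn->vk", X, y[None, :] - p)
    converged = (np.abs(score).max(axis=1) < 1e-6) & (np.abs(eta).max(axis=1) <= 40)
    ses = np.full(active.size, np.nan)
    bs = np.full(active.size, np.nan)
    for t in np.where(converged)[0]:
        info = (X[t] * w[t][:, None]).T @ X[t]
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            continue
        bs[t] = B[t, 1]
        ses[t] = np.sqrt(cov[1, 1])
    out_beta = np.full(m, np.nan)
    out_se = np.full(m, np.nan)
    out_beta[active] = bs
    out_se[active] = ses
    if variant_ids is None:
        variant_ids = [f"snp{j}" for j in range(m)]
    return pd.DataFrame(
        {
            "id": list(variant_ids),
            "beta": out_beta,
            "se": out_se,
            "n": n,
            "missing": ~np.isfinite(out_beta),
        }
    )
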