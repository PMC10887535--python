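"""Hospitalization-level logistic risk model of coding specificity.

Fits ``logit(pi) = alpha + beta'X`` by maximum likelihood (iteratively
reweighted least squares), produces per-hospitalization risk-adjusted
probabilities of a specified diagnosis, Wald odds-ratio tables for the
univariate and multivariate analyses, and ROC/AUC diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .claims_data import CohortTable, CovariateSchema, DesignMatrix, encode_design_matrix

__all__ = [
    "FitOptions",
    "LogisticFit",
    "UnivariateResult",
    "ROCCurve",
    "RankDeficientError",
    "fit_logistic",
    "fit_univariate_series",
    "odds_ratio_table",
    "predict_probabilities",
    "roc_auc",
]


class RankDeficientError(ValueError):
    """Design matrix has aliased (linearly dependent) columns."""


@dataclass(frozen=True)
class FitOptions:
    """IRLS controls.

    ``tol`` is the absolute deviance-change convergence criterion;
    ``instability_bound`` marks quasi-separated coefficients (|beta| above
    ln(100) renders as the ">100" odds ratio seen in claims analyses);
    ``ridge`` adds an optional L2 penalty (off by default so estimates are
    plain ML).
    """

    tol: float = 1e-8
    max_iter: int = 100
    instability_bound: float = float(np.log(100.0))
    ridge: float = 0.0


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit.

    ``coefficients`` align with ``column_names`` (the non-intercept design
    columns); ``covariance`` is the inverse observed information over
    (intercept, coefficients).  ``separation_flags`` lists columns whose
    estimates exceeded the instability bound.
    """

    intercept: float
    coefficients: np.ndarray
    column_names: list[str]
    covariance: np.ndarray
    n_obs: int
    deviance: float
    converged: bool
    iterations: int
    separation_flags: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.coefficients])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


@dataclass
class UnivariateResult:
    """One entry of a univariate series: a fit or a recorded failure."""

    variable: str
    fit: LogisticFit | None
    error: str | None = None


@dataclass
class ROCCurve:
    """ROC over all distinct score thresholds (descending), with
    trapezoidal AUC — equal to the Mann-Whitney concordance with ties
    counted one half."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-300
    return float(-2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))


def fit_logistic(design: DesignMatrix, options: FitOptions | None = None) -> LogisticFit:
    """Fit the logistic model by IRLS.

    Raises :class:`RankDeficientError` naming the aliased columns when the
    design is not full rank, and ``ValueError`` when the outcome carries no
    information (all 0 or all 1).
    """
    opts = options or FitOptions()
    X = np.asarray(design.X, dtype=float)
    y = np.asarray(design.y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than columns ({k})")
    if y.min() == y.max():
        raise ValueError("outcome is constant (all 0 or all 1): no information")

    # rank check via pivoted QR; small R diagonals mark aliased columns
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol_rank = diag[0] * max(n, k) * np.finfo(float).eps
    aliased = [design.column_names[piv[i]] for i in range(k) if diag[i] <= tol_rank]
    if aliased:
        raise RankDeficientError(f"aliased design column(s): {aliased}")

    beta = np.zeros(k)
    p_bar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[0] = np.log(p_bar / (1 - p_bar))
    dev = np.inf
    converged = False
    it = 0
    info = None
    for it in range(1, opts.max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        info = X.T @ Xw
        if opts.ridge > 0.0:
            info = info + opts.ridge * np.eye(k)
        rhs = Xw.T @ z if opts.ridge == 0.0 else X.T @ (w * z)
        try:
            beta = np.linalg.solve(info, rhs)
        except np.linalg.LinAlgError:
            # near-singular weight collapse under separation: tiny jitter
            beta = np.linalg.solve(info + 1e-10 * np.eye(k), rhs)
        new_dev = _deviance(y, expit(np.clip(X @ beta, -30.0, 30.0)))
        if abs(dev - new_dev) < opts.tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev
    # final information and covariance at the optimum
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    if opts.ridge > 0.0:
        info = info + opts.ridge * np.eye(k)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)

    flags = [
        design.column_names[j]
        for j in range(1, k)
        if abs(beta[j]) > opts.instability_bound
    ]
    return LogisticFit(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        column_names=list(design.column_names[1:]),
        covariance=cov,
        n_obs=n,
        deviance=dev,
        converged=converged,
        iterations=it,
        separation_flags=flags,
    )


def fit_univariate_series(
    table: CohortTable,
    outcome_role: str | None = None,
    options: FitOptions | None = None,
) -> list[UnivariateResult]:
    """One single-covariate fit per schema variable.

    Failures (separation, constant covariate, ...) are recorded per
    variable and the remaining variables still get fits.
    """
    if outcome_role is not None:
        mask = table.data["diagnosis_role"] == outcome_role
        table = CohortTable(
            table.data.loc[mask].reset_index(drop=True),
            table.schema,
            list(table.provenance),
        )
    results: list[UnivariateResult] = []
    for v in table.schema.variables:
        sub = CohortTable(table.data, CovariateSchema((v,), {}), [])
        try:
            fit = fit_logistic(encode_design_matrix(sub), options)
            results.append(UnivariateResult(v.name, fit))
        except Exception as exc:  # noqa: BLE001 — recorded, not swallowed
            results.append(UnivariateResult(v.name, None, error=str(exc)))
    return results


def _split_column(name: str) -> tuple[str, str]:
    if "=" in name:
        var, lev = name.split("=", 1)
        return var, lev
    return name, ""


def odds_ratio_table(
    fits: LogisticFit | Sequence[UnivariateResult],
    confidence: float = 0.95,
    analysis: str = "multivariate",
) -> pd.DataFrame:
    """Wald odds-ratio table: OR, CI, two-sided p per design column.

    Quasi-separated columns keep their numeric values but their display
    strings render as ``>100`` (or ``<0.01``) with CI ``0.000-Inf``, the
    convention used for unstable claims-model estimates.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must lie in (0, 1), got {confidence}")
    z = norm.ppf(0.5 + confidence / 2.0)

    if isinstance(fits, LogisticFit):
        pairs: list[tuple[str, LogisticFit]] = [(analysis, fits)]
    else:
        pairs = [
            ("univariate", r.fit) for r in fits if r.fit is not None
        ]
        analysis = "univariate"

    rows = []
    for label, fit in pairs:
        ses = fit.standard_errors[1:]
        for j, name in enumerate(fit.column_names):
            b, se = float(fit.coefficients[j]), float(ses[j])
            var, lev = _split_column(name)
            with np.errstate(over="ignore"):  # separated coefs overflow to inf
                orv = float(np.exp(b))
                lo, hi = float(np.exp(b - z * se)), float(np.exp(b + z * se))
            p = float(2.0 * norm.sf(abs(b) / se)) if se > 0 else float("nan")
            flagged = name in fit.separation_flags
            if flagged:
                or_disp = ">100" if b > 0 else "<0.01"
                ci_disp = "0.000-Inf"
            else:
                or_disp = f"{orv:.3f}"
                ci_disp = f"{lo:.3f}-{hi:.3f}"
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "odds_ratio": orv,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": p,
                    "analysis": label if label != "multivariate" else analysis,
                    "flagged": flagged,
                    "or_display": or_disp,
                    "ci_display": ci_disp,
                }
            )
    return pd.DataFrame(rows)


def predict_probabilities(fit: LogisticFit, design: DesignMatrix) -> np.ndarray:
    """Risk-adjusted probabilities ``pi = expit(alpha + beta'x)`` per row."""
    expected = ["intercept"] + fit.column_names
    if list(design.column_names) != expected:
        raise ValueError(
            f"design columns {design.column_names} do not match fit columns {expected}"
        )
    eta = design.X @ fit.params
    return expit(np.clip(eta, -700, 700))


def roc_auc(probabilities: np.ndarray, outcomes: np.ndarray) -> ROCCurve:
    """ROC curve over distinct thresholds and its trapezoidal AUC.

    The AUC equals the Mann-Whitney probability of concordance with tied
    scores counted one half.  Requires both outcome classes present.
    """
    s = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("probabilities and outcomes must be aligned 1-d vectors")
    P = int(np.sum(y == 1))
    N = int(np.sum(y == 0))
    if P == 0 or N == 0:
        raise ValueError("both outcome classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # group rows sharing a score so ties enter each threshold together
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    ends = np.append(distinct, s_sorted.size - 1)
    cum_tp = np.cumsum(y_sorted == 1)[ends]
    cum_fp = np.cumsum(y_sorted == 0)[ends]
    thresholds = np.concatenate([[np.inf], s_sorted[ends]])
    tpr = np.concatenate([[0.0], cum_tp / P])
    fpr = np.concatenate([[0.0], cum_fp / N])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
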