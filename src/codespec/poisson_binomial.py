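"""Exact Poisson Binomial distribution for facility specificity counts.

A facility's total count of specified diagnoses is a sum of independent
Bernoulli trials with unequal, risk-adjusted success probabilities — a
Poisson Binomial (PB) law.  This module computes its pmf exactly by
iterative convolution (adding one trial at a time), the cdf, the discrete
peer-standard quantiles ``(Q_L, Q_U)`` at a two-one-sided threshold ``t``,
inclusive-tail p-values for an observed count, closed-form moments, and a
continuity-corrected normal approximation to the cdf.

Discrete quantile convention
----------------------------
A discrete law cannot place exact mass ``t`` in a tail, so the quantiles
are defined conservatively:

* ``Q_L`` — smallest integer ``q`` with ``P(X <= q) >= t``;
* ``Q_U`` — largest integer ``q`` with ``P(X >= q) >= t``.

With inclusive-tail p-values (``p_under = P(X <= obs)``,
``p_over = P(X >= obs)``) flagging ``p < t`` is then equivalent to
``obs < Q_L`` / ``obs > Q_U`` and the per-side false-flag rate under the
null is at most ``t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "PoissonBinomialDistribution",
    "PBTailResult",
    "pb_pmf",
    "pb_cdf",
    "pb_quantiles",
    "pb_pvalues",
    "pb_moments",
    "pb_cdf_normal_approx",
    "pb_exact_flag_rates",
]

#: drift beyond this triggers pmf renormalization
_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PoissonBinomialDistribution:
    """Probability vector of one facility's hospitalization-level trials."""

    probabilities: np.ndarray = field()

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1:
            raise ValueError("probability vector must be one-dimensional")
        if p.size == 0:
            raise ValueError("probability vector must be non-empty")
        if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probabilities", p)

    @property
    def n(self) -> int:
        return int(self.probabilities.size)


@dataclass(frozen=True)
class PBTailResult:
    """Tail summary of an observed count against a facility's PB law.

    ``p_under`` and ``p_over`` are inclusive tails so they share the pmf
    mass at ``observed`` (hence ``p_under + p_over >= 1``).
    """

    observed: int
    p_under: float
    p_over: float
    QL: int
    QU: int
    threshold: float


def pb_pmf(dist: PoissonBinomialDistribution) -> np.ndarray:
    """Exact pmf over counts ``0..n`` via O(n^2) convolution.

    Adds one Bernoulli trial at a time in plain double precision; if the
    running total drifts from 1 beyond 1e-9 the vector is renormalized.
    """
    p = dist.probabilities
    n = p.size
    pmf = np.zeros(n + 1)
    pmf[0] = 1.0
    for i in range(1, n + 1):
        pi = p[i - 1]
        pmf[1 : i + 1] = pmf[1 : i + 1] * (1.0 - pi) + pmf[0:i] * pi
        pmf[0] *= 1.0 - pi
    total = pmf.sum()
    if abs(total - 1.0) > _SUM_TOL:
        pmf /= total
    return pmf


def pb_cdf(dist: PoissonBinomialDistribution, k: int) -> float:
    """``P(X <= k)``; 0 below the support and 1 at or above ``n``."""
    if k < 0:
        return 0.0
    if k >= dist.n:
        return 1.0
    cdf = np.cumsum(pb_pmf(dist))
    return float(min(cdf[k], 1.0))


def _quantiles_from_cdf(cdf: np.ndarray, t: float) -> tuple[int, int]:
    n = cdf.size - 1
    ql = int(np.searchsorted(cdf, t, side="left"))
    # survival sf[q] = P(X >= q) = 1 - cdf[q-1]; nonincreasing in q
    sf = np.empty(n + 1)
    sf[0] = 1.0
    sf[1:] = 1.0 - cdf[:-1]
    qu = int(np.searchsorted(-sf, -t, side="right")) - 1
    return ql, qu


def pb_quantiles(dist: PoissonBinomialDistribution, t: float) -> tuple[int, int]:
    """Discrete peer-standard bounds ``(Q_L, Q_U)`` at threshold ``t``.

    ``t = 0.025`` gives the discrete 2.5th/97.5th percentiles used for
    two-one-sided facility flagging.
    """
    if not 0.0 <= t < 0.5:
        raise ValueError(f"threshold t must lie in [0, 0.5), got {t}")
    cdf = np.cumsum(pb_pmf(dist))
    return _quantiles_from_cdf(cdf, t)


def pb_pvalues(
    dist: PoissonBinomialDistribution,
    observed: int,
    threshold: float = 0.025,
    mid_p: bool = False,
) -> PBTailResult:
    """Inclusive-tail p-values and quantiles for an observed count.

    With ``mid_p=True`` half the point mass at ``observed`` is counted in
    each tail instead (``P(X < obs) + pmf(obs)/2``); off by default since
    facility classification uses the plain cdf.
    """
    n = dist.n
    if not isinstance(observed, (int, np.integer)):
        raise TypeError("observed count must be an integer")
    if not 0 <= observed <= n:
        raise ValueError(f"observed count {observed} outside [0, {n}]")
    if not 0.0 <= threshold < 0.5:
        raise ValueError(f"threshold t must lie in [0, 0.5), got {threshold}")
    pmf = pb_pmf(dist)
    cdf = np.cumsum(pmf)
    p_under = float(min(cdf[observed], 1.0))
    p_over = float(min(1.0 - (cdf[observed - 1] if observed > 0 else 0.0), 1.0))
    if mid_p:
        half = 0.5 * float(pmf[observed])
        p_under -= half
        p_over -= half
    ql, qu = _quantiles_from_cdf(cdf, threshold)
    return PBTailResult(
        observed=int(observed),
        p_under=p_under,
        p_over=p_over,
        QL=ql,
        QU=qu,
        threshold=float(threshold),
    )


def pb_moments(dist: PoissonBinomialDistribution) -> tuple[float, float]:
    """Mean ``sum(pi)`` and variance ``sum(pi * (1 - pi))``."""
    p = dist.probabilities
    mean = math.fsum(p.tolist())
    variance = math.fsum((p * (1.0 - p)).tolist())
    return mean, variance


def pb_cdf_normal_approx(dist: PoissonBinomialDistribution, k: int) -> float:
    """Continuity-corrected normal approximation to ``P(X <= k)``.

    A scalability aid for very large facilities only; never used for
    classification unless explicitly requested.
    """
    mean, variance = pb_moments(dist)
    if variance <= 0.0:
        raise ValueError("normal approximation requires positive variance")
    return float(norm.cdf((k + 0.5 - mean) / math.sqrt(variance)))


def pb_exact_flag_rates(
    dist: PoissonBinomialDistribution, t: float
) -> tuple[float, float]:
    """Exact per-side null flag probabilities ``P(X < Q_L)`` and ``P(X > Q_U)``.

    These are the conservative attained levels of the discrete two-sided
    test; each is at most ``t`` by construction of the quantiles.
    """
    if not 0.0 <= t < 0.5:
        raise ValueError(f"threshold t must lie in [0, 0.5), got {t}")
    cdf = np.cumsum(pb_pmf(dist))
    ql, qu = _quantiles_from_cdf(cdf, t)
    under = float(cdf[ql - 1]) if ql > 0 else 0.0
    over = float(1.0 - cdf[qu]) if qu < dist.n else 0.0
    return min(max(under, 0.0), 1.0), min(max(over, 0.0), 1.0)
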