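"""Facility-level aggregation, peer-standard classification, and exports.

Groups risk-adjusted probabilities by facility, compares each facility's
observed specified-diagnosis count to the discrete bounds of its Poisson
Binomial law at threshold ``t`` (default 0.025 per side), and produces
the report/plot-data products: a per-facility results table, caterpillar
plot data, and the state odds-ratio table underlying choropleth maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_data import CohortTable, encode_design_matrix
from .poisson_binomial import PoissonBinomialDistribution, pb_moments, pb_pvalues
from .risk_model import LogisticFit, predict_probabilities

__all__ = [
    "FacilityResult",
    "ProfilingReport",
    "aggregate_by_facility",
    "classify_facility",
    "profile_facilities",
    "export_caterpillar",
    "extract_state_ors",
]

CLASSIFICATIONS = ("under", "in_line", "over")


@dataclass(frozen=True)
class FacilityResult:
    """One facility against its peers.

    ``low_information`` marks facilities whose PB law cannot flag at the
    threshold in either direction (QL = 0 and QU = n), typically tiny
    facilities; they are reported, not suppressed.
    """

    facility_id: str
    n: int
    observed: int
    expected: float
    QL: int
    QU: int
    p_under: float
    p_over: float
    classification: str
    threshold: float
    low_information: bool = False


@dataclass
class ProfilingReport:
    """All facility results for one outcome role and threshold."""

    results: list[FacilityResult]
    threshold: float
    outcome_role: str = ""
    provenance: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {k: 0 for k in CLASSIFICATIONS}
        for r in self.results:
            c[r.classification] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "facility_id": r.facility_id,
                    "n": r.n,
                    "observed": r.observed,
                    "expected": r.expected,
                    "QL": r.QL,
                    "QU": r.QU,
                    "p_under": r.p_under,
                    "p_over": r.p_over,
                    "classification": r.classification,
                    "threshold": r.threshold,
                    "low_information": r.low_information,
                }
                for r in self.results
            ]
        )


def aggregate_by_facility(
    table: CohortTable, probabilities: np.ndarray
) -> dict[str, tuple[np.ndarray, int]]:
    """Partition row probabilities by facility with observed counts.

    Returns ``facility_id -> (probability vector, observed specified
    count)``; group sizes sum to the number of rows.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape[0] != len(table):
        raise ValueError(
            f"probabilities length {probs.shape[0]} does not match "
            f"{len(table)} cohort rows"
        )
    outcomes = table.data["outcome"].to_numpy(dtype=int)
    out: dict[str, tuple[np.ndarray, int]] = {}
    grouped = table.data.groupby("facility_id", sort=True).indices
    for fid, idx in grouped.items():
        out[str(fid)] = (probs[idx], int(outcomes[idx].sum()))
    return out


def classify_facility(
    group: tuple[np.ndarray, int], t: float, facility_id: str = ""
) -> FacilityResult:
    """Classify one facility's observed count against its PB law.

    ``under`` iff the inclusive lower-tail p-value is below ``t``,
    ``over`` iff the upper one is; otherwise ``in_line``.  The two can
    never hold together since the tails share the mass at the observed
    count.
    """
    probs, observed = group
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty facility group")
    if not 0.0 <= t < 0.5:
        raise ValueError(f"threshold t must lie in [0, 0.5), got {t}")
    # t = 0 is the degenerate empty rejection region: nothing can flag
    dist = PoissonBinomialDistribution(probs)
    tail = pb_pvalues(dist, int(observed), threshold=t)
    if tail.p_under < t:
        cls = "under"
    elif tail.p_over < t:
        cls = "over"
    else:
        cls = "in_line"
    mean, _ = pb_moments(dist)
    return FacilityResult(
        facility_id=facility_id,
        n=dist.n,
        observed=int(observed),
        expected=mean,
        QL=tail.QL,
        QU=tail.QU,
        p_under=tail.p_under,
        p_over=tail.p_over,
        classification=cls,
        threshold=t,
        low_information=(tail.QL == 0 and tail.QU == dist.n),
    )


def profile_facilities(
    table: CohortTable, fit: LogisticFit, t: float = 0.025
) -> ProfilingReport:
    """Full second stage: predict, aggregate, classify every facility.

    Output is ordered by facility id for determinism.
    """
    design = encode_design_matrix(table)
    probs = predict_probabilities(fit, design)
    groups = aggregate_by_facility(table, probs)
    results = [
        classify_facility(groups[fid], t, facility_id=fid)
        for fid in sorted(groups)
    ]
    role = ""
    roles = table.data["diagnosis_role"].unique()
    if len(roles) == 1:
        role = str(roles[0])
    return ProfilingReport(
        results=results,
        threshold=t,
        outcome_role=role,
        provenance=list(table.provenance),
    )


def export_caterpillar(
    report: ProfilingReport, sample_size: int, seed: int = 0
) -> pd.DataFrame:
    """Seeded facility sample for interval (caterpillar) plotting.

    Rows carry observed count, expected count and the (QL, QU) bounds,
    ordered by expected count; same seed, same sample.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be at least 1")
    if sample_size > len(report.results):
        raise ValueError(
            f"sample_size {sample_size} exceeds {len(report.results)} facilities"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(report.results), size=sample_size, replace=False)
    chosen = [report.results[i] for i in sorted(idx)]
    chosen.sort(key=lambda r: (r.expected, r.facility_id))
    return pd.DataFrame(
        [
            {
                "facility": r.facility_id,
                "n": r.n,
                "observed": r.observed,
                "expected": r.expected,
                "QL": r.QL,
                "QU": r.QU,
                "classification": r.classification,
            }
            for r in chosen
        ]
    )


def extract_state_ors(
    or_table: pd.DataFrame,
    reference_state: str,
    state_variable: str = "state",
    over_bins: tuple[float, float] = (2.0, 4.0),
) -> pd.DataFrame:
    """Per-state adjusted OR table with display bins for mapping.

    Bins: ``reference`` (the reference state, OR 1 by definition),
    ``non_significant`` (CI spans 1), ``under`` (OR < 1, significant),
    and three over-specificity ranges ``over_low`` (1, b1], ``over_mid``
    (b1, b2], ``over_high`` (> b2) with configurable cut points.
    """
    rows = or_table[or_table["variable"] == state_variable]
    if rows.empty:
        raise ValueError(f"no rows for state variable {state_variable!r} in OR table")
    b1, b2 = over_bins
    out = [
        {
            "state": reference_state,
            "odds_ratio": 1.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "p_value": np.nan,
            "bin": "reference",
        }
    ]
    for _, r in rows.iterrows():
        orv, lo, hi = r["odds_ratio"], r["ci_low"], r["ci_high"]
        significant = (lo > 1.0) or (hi < 1.0)
        if not significant:
            b = "non_significant"
        elif orv < 1.0:
            b = "under"
        elif orv <= b1:
            b = "over_low"
        elif orv <= b2:
            b = "over_mid"
        else:
            b = "over_high"
        out.append(
            {
                "state": r["level"],
                "odds_ratio": float(orv),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_value": float(r["p_value"]),
                "bin": b,
            }
        )
    return pd.DataFrame(out).sort_values("state", kind="stable").reset_index(drop=True)
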