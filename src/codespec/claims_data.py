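"""Claims records, cohort construction, and design-matrix encoding.

Reads delimited hospitalization extracts (one row per inpatient stay),
validates them against a declared covariate schema, applies the cohort
rules (first stay per patient, rare-category grouping, specificity
labelling of ICD-10-CM depression codes), and produces the dummy-coded
design matrix consumed by the logistic risk model.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "Variable",
    "CovariateSchema",
    "HospitalizationRecord",
    "CohortTable",
    "DesignMatrix",
    "DEFAULT_UNSPECIFIED_MAP",
    "read_claims_table",
    "write_claims_table",
    "select_first_stays",
    "derive_specificity_label",
    "group_rare_categories",
    "encode_design_matrix",
    "summarize_cohort",
]

REQUIRED_COLUMNS = (
    "patient_id",
    "facility_id",
    "outcome",
    "diagnosis_role",
    "discharge_date",
)

DIAGNOSIS_ROLES = ("principal", "secondary")

#: Unspecified depression codes.  The literature singles out F32.A
#: (unspecified depression); F32.9 / F33.9 are the "unspecified" leaves of
#: the depressive-episode and recurrent-MDD categories.  User-overridable:
#: the full map is configuration, not a constant of the method.
DEFAULT_UNSPECIFIED_MAP = frozenset({"F32.9", "F33.9", "F32.A"})


class SchemaError(ValueError):
    """Schema/column-level problem (missing column, bad declaration)."""


class ValidationError(ValueError):
    """Row-level problem; message carries 1-based data row numbers."""


@dataclass(frozen=True)
class Variable:
    """One covariate declaration.

    ``levels`` are the raw levels as they appear in the extract;
    grouping rules on the schema may merge them.  ``transform`` is
    ``"log"`` (natural log) or ``"none"`` and only valid on strictly
    positive continuous variables.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()
    reference: str | None = None
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"{self.name}: kind must be continuous or categorical")
        if self.transform not in ("none", "log"):
            raise SchemaError(f"{self.name}: transform must be none or log")
        if self.kind == "categorical":
            if not self.levels:
                raise SchemaError(f"{self.name}: categorical variable needs levels")
            if self.reference is None or self.reference not in self.levels:
                raise SchemaError(
                    f"{self.name}: reference level must be among the allowed levels"
                )
            if self.transform != "none":
                raise SchemaError(f"{self.name}: transform applies to continuous only")
        else:
            if self.levels or self.reference is not None:
                raise SchemaError(f"{self.name}: continuous variable takes no levels")


@dataclass
class CovariateSchema:
    """Ordered covariate declarations plus raw-level grouping rules.

    ``grouping_rules`` maps ``variable -> {raw level -> grouped level}``;
    applying them (at read time or via :func:`group_rare_categories`)
    yields the *resolved* schema whose levels are the grouped ones.
    """

    variables: tuple[Variable, ...]
    grouping_rules: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        for var in self.grouping_rules:
            v = self.get(var)
            if v is None:
                raise SchemaError(f"grouping rule references unknown variable {var!r}")
            if v.kind != "categorical":
                raise SchemaError(f"grouping rule on non-categorical variable {var!r}")

    def get(self, name: str) -> Variable | None:
        for v in self.variables:
            if v.name == name:
                return v
        return None

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def resolved(self) -> "CovariateSchema":
        """Schema after grouping: merged levels, empty grouping rules."""
        out = []
        for v in self.variables:
            rules = self.grouping_rules.get(v.name, {})
            if v.kind != "categorical" or not rules:
                out.append(v)
                continue
            seen: list[str] = []
            for lev in v.levels:
                g = rules.get(lev, lev)
                if g not in seen:
                    seen.append(g)
            ref = rules.get(v.reference, v.reference)
            out.append(replace(v, levels=tuple(seen), reference=ref))
        return CovariateSchema(tuple(out), {})

    def map_level(self, name: str, value: str) -> str | None:
        """Resolve a raw categorical value, or None if not allowed."""
        v = self.get(name)
        if v is None or v.kind != "categorical":
            return None
        rules = self.grouping_rules.get(name, {})
        if value in rules:
            return rules[value]
        resolved_levels = {rules.get(l, l) for l in v.levels}
        if value in v.levels or value in resolved_levels:
            return rules.get(value, value)
        return None

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping) or "variables" not in doc:
            raise SchemaError(f"{path}: schema file needs a 'variables' section")
        variables = []
        for entry in doc["variables"]:
            variables.append(
                Variable(
                    name=str(entry["name"]),
                    kind=str(entry["kind"]),
                    levels=tuple(str(l) for l in entry.get("levels", ()) or ()),
                    reference=(
                        str(entry["reference"]) if "reference" in entry else None
                    ),
                    transform=str(entry.get("transform", "none")),
                )
            )
        grouping = {
            str(var): {str(k): str(v) for k, v in rules.items()}
            for var, rules in (doc.get("grouping") or {}).items()
        }
        return cls(tuple(variables), grouping)

    def to_yaml(self, path) -> None:
        doc: dict = {"variables": []}
        for v in self.variables:
            entry: dict = {"name": v.name, "kind": v.kind}
            if v.kind == "categorical":
                entry["levels"] = list(v.levels)
                entry["reference"] = v.reference
            if v.transform != "none":
                entry["transform"] = v.transform
            doc["variables"].append(entry)
        if self.grouping_rules:
            doc["grouping"] = {k: dict(v) for k, v in self.grouping_rules.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class HospitalizationRecord:
    """One inpatient stay: outcome S, covariates X, identifiers."""

    patient_id: str
    facility_id: str
    outcome: int
    diagnosis_role: str
    covariates: dict
    discharge_date: _dt.date


@dataclass
class CohortTable:
    """A validated cohort: one row per hospitalization plus its schema.

    ``data`` holds the required columns and one column per schema
    variable; ``provenance`` accumulates free-text notes (source file,
    filters applied and their removal counts).
    """

    data: pd.DataFrame
    schema: CovariateSchema
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def records(self) -> Iterator[HospitalizationRecord]:
        names = self.schema.names
        for row in self.data.itertuples(index=False):
            d = row._asdict()
            yield HospitalizationRecord(
                patient_id=d["patient_id"],
                facility_id=d["facility_id"],
                outcome=int(d["outcome"]),
                diagnosis_role=d["diagnosis_role"],
                covariates={n: d[n] for n in names},
                discharge_date=_dt.date.fromisoformat(str(d["discharge_date"])[:10]),
            )

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.schema, list(self.provenance))


@dataclass
class DesignMatrix:
    """Encoded design: intercept, dummy indicators, transformed continuous.

    ``column_names[0]`` is always ``"intercept"``; categorical variables
    contribute one indicator per non-reference level named
    ``"variable=level"``; log-transformed continuous columns are named
    ``"log(variable)"``.
    """

    column_names: list[str]
    X: np.ndarray
    y: np.ndarray
    row_index: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def _parse_outcome(series: pd.Series) -> np.ndarray:
    vals = series.astype(str).str.strip()
    bad = ~vals.isin(["0", "1"])
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 1)[:5].tolist()
        raise ValidationError(f"outcome must be 0/1; bad value at data row(s) {rows}")
    return vals.astype(int).to_numpy()


def read_claims_table(path, schema: CovariateSchema) -> CohortTable:
    """Read an RFC 4180 CSV claims extract into a validated cohort.

    The header must name every schema variable plus ``patient_id``,
    ``facility_id``, ``outcome``, ``diagnosis_role``, ``discharge_date``.
    Unknown categorical levels are rejected unless the schema's grouping
    rules map them; mapped values are stored grouped and the returned
    table carries the resolved schema.  Lines starting with ``#`` are
    provenance headers and skipped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if df.empty:
        raise ValidationError(f"{path}: empty claims file")
    needed = list(REQUIRED_COLUMNS) + schema.names
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    out = pd.DataFrame(index=df.index)
    out["patient_id"] = df["patient_id"].astype(str)
    out["facility_id"] = df["facility_id"].astype(str)
    out["outcome"] = _parse_outcome(df["outcome"])
    roles = df["diagnosis_role"].str.strip()
    bad_role = ~roles.isin(DIAGNOSIS_ROLES)
    if bad_role.any():
        rows = (np.flatnonzero(bad_role.to_numpy()) + 1)[:5].tolist()
        raise ValidationError(f"invalid diagnosis_role at data row(s) {rows}")
    out["diagnosis_role"] = roles
    dates = pd.to_datetime(df["discharge_date"], format="ISO8601", errors="coerce")
    if dates.isna().any():
        rows = (np.flatnonzero(dates.isna().to_numpy()) + 1)[:5].tolist()
        raise ValidationError(f"unparseable discharge_date at data row(s) {rows}")
    out["discharge_date"] = dates.dt.strftime("%Y-%m-%d")

    for v in schema.variables:
        col = df[v.name].astype(str).str.strip()
        if v.kind == "continuous":
            parsed = pd.to_numeric(col, errors="coerce")
            if parsed.isna().any():
                rows = (np.flatnonzero(parsed.isna().to_numpy()) + 1)[:5].tolist()
                raise ValidationError(
                    f"unparseable value for {v.name!r} at data row(s) {rows}"
                )
            out[v.name] = parsed.to_numpy(dtype=float)
        else:
            mapped = col.map(lambda x: schema.map_level(v.name, x))
            if mapped.isna().any():
                idx = np.flatnonzero(mapped.isna().to_numpy())
                rows = (idx + 1)[:5].tolist()
                examples = col.iloc[idx[:3]].tolist()
                raise ValidationError(
                    f"unknown level(s) {examples} for {v.name!r} "
                    f"at data row(s) {rows}"
                )
            out[v.name] = mapped
    return CohortTable(
        out.reset_index(drop=True),
        schema.resolved(),
        provenance=[f"read {len(out)} records from {path}"],
    )


def write_claims_table(table: CohortTable, path, header_lines: Sequence[str] = ()) -> None:
    """Write a cohort back to the claims CSV dialect (round-trip safe)."""
    cols = list(REQUIRED_COLUMNS) + table.schema.names
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.data[cols].to_csv(fh, index=False)


def select_first_stays(table: CohortTable) -> CohortTable:
    """Keep each patient's earliest stay (per diagnosis role).

    Restricting to one hospitalization per patient avoids excess influence
    from patients with many recurring stays.  Ties on the earliest date are
    broken by file order (first record wins) with a logged warning.
    """
    df = table.data
    order = df["discharge_date"].to_numpy()
    # stable sort by date preserves file order within ties
    sorted_df = df.iloc[np.argsort(order, kind="stable")]
    keep = sorted_df.drop_duplicates(["patient_id", "diagnosis_role"], keep="first")
    removed = len(df) - len(keep)

    firsts = sorted_df.groupby(["patient_id", "diagnosis_role"], sort=False)
    n_ties = int(
        sum(
            (g["discharge_date"] == g["discharge_date"].iloc[0]).sum() > 1
            for _, g in firsts
        )
    )
    if n_ties:
        logger.warning(
            "select_first_stays: %d patient/role group(s) tied on the earliest "
            "discharge date; kept the first record in file order",
            n_ties,
        )
    out = df.loc[df.index.isin(keep.index)].reset_index(drop=True)
    prov = list(table.provenance) + [
        f"select_first_stays: removed {removed} of {len(df)} records"
    ]
    return CohortTable(out, table.schema, prov)


def _matches(code: str, pattern: str) -> bool:
    if pattern.endswith("*"):
        return code.startswith(pattern[:-1])
    return code == pattern


def derive_specificity_label(
    icd10_codes: Sequence[str],
    role: str,
    unspecified_map: frozenset | set = DEFAULT_UNSPECIFIED_MAP,
) -> int:
    """Binary specificity outcome from depression ICD-10-CM codes.

    Principal role: 1 iff the single principal code is not unspecified.
    Secondary role: 1 iff *at least one* depression secondary code is not
    unspecified (a hospitalization can carry several depression secondary
    diagnoses).  Codes must belong to the F32/F33 depression cohort.
    Patterns in ``unspecified_map`` may end in ``*`` for prefix matching.
    """
    if role not in DIAGNOSIS_ROLES:
        raise ValueError(f"role must be one of {DIAGNOSIS_ROLES}")
    codes = [str(c).strip().upper() for c in icd10_codes]
    if not codes:
        raise ValueError("empty ICD-10 code list")
    for c in codes:
        if not (c.startswith("F32") or c.startswith("F33")):
            raise ValueError(f"code {c!r} outside the F32/F33 depression cohort")
    patterns = {p.upper() for p in unspecified_map}
    if role == "principal":
        if len(codes) != 1:
            raise ValueError("principal role carries exactly one diagnosis code")
        return int(not any(_matches(codes[0], p) for p in patterns))
    return int(any(not any(_matches(c, p) for p in patterns) for c in codes))


def group_rare_categories(table: CohortTable) -> CohortTable:
    """Apply the schema's grouping rules to an in-memory cohort.

    Low-count levels with similar meanings (e.g. charity and indigent
    payors) or adjacent ordered bands (e.g. ages 1-4 and 5-9 into 0-9)
    are merged; counts are conserved and no rows are dropped.
    """
    rules = table.schema.grouping_rules
    if not rules:
        return table
    df = table.data.copy()
    for var, mapping in rules.items():
        df[var] = df[var].map(lambda x: mapping.get(x, x))
    prov = list(table.provenance) + [
        f"group_rare_categories: applied rules for {sorted(rules)}"
    ]
    return CohortTable(df, table.schema.resolved(), prov)


def encode_design_matrix(table: CohortTable) -> DesignMatrix:
    """Dummy-code the cohort into the logistic design matrix.

    Reference-level coding: each categorical variable with k levels yields
    k-1 indicator columns (reference omitted).  Continuous variables pass
    through their transform; under the natural-log transform a zero-day
    (same-day) stay is clamped to 1 day first and negative values are
    rejected.
    """
    df = table.data
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for v in table.schema.variables:
        if v.kind == "categorical":
            vals = df[v.name].astype(str)
            allowed = set(v.levels)
            bad = ~vals.isin(allowed)
            if bad.any():
                rows = (np.flatnonzero(bad.to_numpy()) + 1)[:5].tolist()
                raise ValidationError(
                    f"value outside allowed levels for {v.name!r} at row(s) {rows}"
                )
            for lev in v.levels:
                if lev == v.reference:
                    continue
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{v.name}={lev}")
        else:
            x = df[v.name].to_numpy(dtype=float)
            if v.transform == "log":
                x = x.copy()
                x[x == 0.0] = 1.0  # same-day stays count as one day
                if np.any(x < 0.0):
                    rows = (np.flatnonzero(x < 0.0) + 1)[:5].tolist()
                    raise ValidationError(
                        f"negative value under log transform for {v.name!r} "
                        f"at row(s) {rows}"
                    )
                x = np.log(x)
                names.append(f"log({v.name})")
            else:
                names.append(v.name)
            cols.append(x)
    X = np.column_stack(cols)
    y = df["outcome"].to_numpy(dtype=int)
    return DesignMatrix(names, X, y, np.arange(n))


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Descriptive statistics: counts/percentages and means/SDs.

    One row per categorical level (count, percent of total) and one row
    per continuous variable (mean, sample SD on the analysis scale, i.e.
    after any log transform), in schema order.
    """
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty cohort")
    df = table.data
    n = len(df)
    rows = []
    for v in table.schema.variables:
        if v.kind == "categorical":
            counts = df[v.name].value_counts()
            for lev in v.levels:
                c = int(counts.get(lev, 0))
                rows.append(
                    {
                        "variable": v.name,
                        "level": lev,
                        "count": c,
                        "percent": 100.0 * c / n,
                        "mean": np.nan,
                        "sd": np.nan,
                    }
                )
        else:
            x = df[v.name].to_numpy(dtype=float)
            label = v.name
            if v.transform == "log":
                x = np.log(np.where(x == 0.0, 1.0, x))
                label = f"log({v.name})"
            rows.append(
                {
                    "variable": label,
                    "level": "",
                    "count": n,
                    "percent": np.nan,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
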