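import numpy as np
import pandas as pd
import pytest

from codespec.claims_data import CohortTable, CovariateSchema, Variable


def make_cohort(rows: list[dict], schema: CovariateSchema) -> CohortTable:
    """Build an in-memory cohort from row dicts (test helper)."""
    df = pd.DataFrame(rows)
    for col, default in (
        ("patient_id", None),
        ("facility_id", "F1"),
        ("outcome", 0),
        ("diagnosis_role", "principal"),
        ("discharge_date", "2022-06-01"),
    ):
        if col not in df.columns:
            if default is None:
                df[col] = [f"P{i}" for i in range(len(df))]
            else:
                df[col] = default
        elif default is not None:
            df[col] = df[col].fillna(default)
    return CohortTable(df, schema, ["test fixture"])


@pytest.fixture
def sex_schema() -> CovariateSchema:
    return CovariateSchema(
        (Variable("sex", "categorical", ("Female", "Male"), "Female"),), {}
    )


@pytest.fixture
def two_by_two_cohort(sex_schema) -> CohortTable:
    """2x2 fixture: exposed (Male) a=40 S=1 / b=60 S=0; unexposed c=20/d=80."""
    rows = []
    for sex, s1, s0 in (("Male", 40, 60), ("Female", 20, 80)):
        rows += [{"sex": sex, "outcome": 1}] * s1
        rows += [{"sex": sex, "outcome": 0}] * s0
    return make_cohort(rows, sex_schema)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
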