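"""Claims reading, cohort rules, encoding, and summaries."""

import numpy as np
import pandas as pd
import pytest

from codespec.claims_data import (
    CovariateSchema,
    SchemaError,
    ValidationError,
    Variable,
    derive_specificity_label,
    encode_design_matrix,
    group_rare_categories,
    read_claims_table,
    select_first_stays,
    summarize_cohort,
    write_claims_table,
)
from conftest import make_cohort

HEADER = "patient_id,facility_id,outcome,diagnosis_role,discharge_date,payor\n"

PAYOR_SCHEMA = CovariateSchema(
    (
        Variable(
            "payor",
            "categorical",
            ("Medicare traditional", "Charity/Indigent"),
            "Medicare traditional",
        ),
    ),
    {"payor": {"Charity": "Charity/Indigent", "Indigent": "Charity/Indigent"}},
)


def write_file(tmp_path, body, header=HEADER):
    path = tmp_path / "claims.csv"
    path.write_text(header + body)
    return path


class TestReadClaims:
    def test_three_row_parse(self, tmp_path):
        path = write_file(
            tmp_path,
            "P1,F1,1,principal,2022-01-05,Medicare traditional\n"
            "P2,F1,0,principal,2022-02-01,Charity/Indigent\n"
            "P3,F2,1,secondary,2022-03-11,Medicare traditional\n",
        )
        table = read_claims_table(path, PAYOR_SCHEMA)
        assert len(table) == 3
        recs = list(table.records())
        assert recs[0].patient_id == "P1"
        assert recs[1].covariates["payor"] == "Charity/Indigent"
        assert recs[2].diagnosis_role == "secondary"

    def test_missing_column_is_schema_error(self, tmp_path):
        path = write_file(
            tmp_path,
            "P1,1,principal,2022-01-05,Medicare traditional\n",
            header="patient_id,outcome,diagnosis_role,discharge_date,payor\n",
        )
        with pytest.raises(SchemaError, match="facility_id"):
            read_claims_table(path, PAYOR_SCHEMA)

    def test_grouping_rule_maps_raw_level(self, tmp_path):
        path = write_file(tmp_path, "P1,F1,1,principal,2022-01-05,Charity\n")
        table = read_claims_table(path, PAYOR_SCHEMA)
        assert table.data.loc[0, "payor"] == "Charity/Indigent"
        # resolved schema exposes only grouped levels
        assert "Charity" not in table.schema.get("payor").levels

    def test_unknown_level_rejected_with_row(self, tmp_path):
        path = write_file(tmp_path, "P1,F1,1,principal,2022-01-05,Venusian HMO\n")
        with pytest.raises(ValidationError, match=r"payor.*row"):
            read_claims_table(path, PAYOR_SCHEMA)

    def test_empty_file_rejected(self, tmp_path):
        path = write_file(tmp_path, "")
        with pytest.raises(ValidationError, match="empty"):
            read_claims_table(path, PAYOR_SCHEMA)

    def test_bad_outcome_names_row(self, tmp_path):
        path = write_file(tmp_path, "P1,F1,2,principal,2022-01-05,Charity\n")
        with pytest.raises(ValidationError, match="outcome"):
            read_claims_table(path, PAYOR_SCHEMA)

    def test_round_trip(self, tmp_path):
        path = write_file(
            tmp_path,
            "P1,F1,1,principal,2022-01-05,Medicare traditional\n"
            "P2,F2,0,secondary,2022-02-01,Charity/Indigent\n",
        )
        table = read_claims_table(path, PAYOR_SCHEMA)
        out = tmp_path / "roundtrip.csv"
        write_claims_table(table, out, header_lines=["written by test"])
        again = read_claims_table(out, table.schema)
        pd.testing.assert_frame_equal(table.data, again.data)


class TestFirstStays:
    def test_earliest_kept(self, sex_schema):
        table = make_cohort(
            [
                {"patient_id": "A", "sex": "Female", "discharge_date": "2022-03-01"},
                {"patient_id": "A", "sex": "Female", "discharge_date": "2022-01-05"},
            ],
            sex_schema,
        )
        out = select_first_stays(table)
        assert len(out) == 1
        assert out.data.loc[0, "discharge_date"] == "2022-01-05"

    def test_unique_patients_unchanged_and_idempotent(self, sex_schema):
        table = make_cohort(
            [{"patient_id": f"P{i}", "sex": "Female"} for i in range(5)], sex_schema
        )
        out = select_first_stays(table)
        assert len(out) == 5
        assert len(select_first_stays(out)) == 5

    def test_duplicate_counting_in_provenance(self, sex_schema):
        rows = [{"patient_id": f"P{i}", "sex": "Female"} for i in range(10)]
        for i in range(3):  # 3 patients gain a later second stay
            rows.append(
                {"patient_id": f"P{i}", "sex": "Female", "discharge_date": "2022-12-01"}
            )
        out = select_first_stays(make_cohort(rows, sex_schema))
        assert len(out) == 10
        assert any("removed 3" in note for note in out.provenance)

    def test_tie_keeps_file_order(self, sex_schema):
        table = make_cohort(
            [
                {"patient_id": "A", "sex": "Female", "facility_id": "F1"},
                {"patient_id": "A", "sex": "Female", "facility_id": "F2"},
            ],
            sex_schema,
        )
        out = select_first_stays(table)
        assert out.data.loc[0, "facility_id"] == "F1"

    def test_roles_are_separate_cohort_keys(self, sex_schema):
        table = make_cohort(
            [
                {"patient_id": "A", "sex": "Female", "diagnosis_role": "principal"},
                {"patient_id": "A", "sex": "Female", "diagnosis_role": "secondary"},
            ],
            sex_schema,
        )
        assert len(select_first_stays(table)) == 2


class TestSpecificityLabel:
    def test_unspecified_principal(self):
        assert derive_specificity_label(["F32.A"], "principal") == 0
        assert derive_specificity_label(["F32.9"], "principal") == 0

    def test_specified_principal(self):
        assert derive_specificity_label(["F33.1"], "principal") == 1

    def test_secondary_at_least_one_specified(self):
        assert derive_specificity_label(["F32.9", "F33.1"], "secondary") == 1

    def test_secondary_all_unspecified(self):
        assert derive_specificity_label(["F32.9"], "secondary") == 0

    def test_monotone_adding_specified_code(self, rng):
        """Adding a specified code never flips a secondary outcome 1 -> 0."""
        pool = ["F32.9", "F33.9", "F32.A", "F32.0", "F32.1", "F33.1", "F33.2"]
        for _ in range(50):
            k = int(rng.integers(1, 5))
            codes = list(rng.choice(pool, size=k))
            before = derive_specificity_label(codes, "secondary")
            after = derive_specificity_label(codes + ["F33.2"], "secondary")
            assert after >= before
            assert after == 1

    def test_errors(self):
        with pytest.raises(ValueError):
            derive_specificity_label([], "principal")
        with pytest.raises(ValueError, match="F32/F33"):
            derive_specificity_label(["I10"], "principal")
        with pytest.raises(ValueError, match="exactly one"):
            derive_specificity_label(["F32.1", "F32.2"], "principal")

    def test_pattern_override(self):
        assert derive_specificity_label(["F32.1"], "principal", {"F32*"}) == 0


class TestGrouping:
    def make_age_table(self):
        schema = CovariateSchema(
            (Variable("age", "categorical", ("1-4", "5-9", "10-14"), "10-14"),),
            {"age": {"1-4": "0-9", "5-9": "0-9"}},
        )
        rows = (
            [{"age": "1-4"}] * 40 + [{"age": "5-9"}] * 168 + [{"age": "10-14"}] * 50
        )
        return make_cohort(rows, schema)

    def test_merged_band_count(self):
        out = group_rare_categories(self.make_age_table())
        assert int((out.data["age"] == "0-9").sum()) == 208
        assert out.schema.get("age").levels == ("0-9", "10-14")

    def test_total_count_conserved(self):
        table = self.make_age_table()
        out = group_rare_categories(table)
        assert len(out) == len(table)
        assert out.data["age"].value_counts().sum() == 258

    def test_empty_rules_identity(self, sex_schema):
        table = make_cohort([{"sex": "Female"}], sex_schema)
        assert group_rare_categories(table) is table

    def test_unknown_variable_in_rules_rejected(self):
        with pytest.raises(SchemaError, match="unknown variable"):
            CovariateSchema(
                (Variable("sex", "categorical", ("F", "M"), "F"),),
                {"ages": {"1-4": "0-9"}},
            )


class TestEncoding:
    def los_schema(self):
        return CovariateSchema(
            (
                Variable("sex", "categorical", ("Female", "Male"), "Female"),
                Variable("length_of_stay", "continuous", transform="log"),
            ),
            {},
        )

    def test_reference_coding(self):
        table = make_cohort(
            [
                {"sex": "Female", "length_of_stay": 4.0, "outcome": 1},
                {"sex": "Male", "length_of_stay": 1.0, "outcome": 0},
            ],
            self.los_schema(),
        )
        design = encode_design_matrix(table)
        assert design.column_names == ["intercept", "sex=Male", "log(length_of_stay)"]
        assert design.X[:, 0].tolist() == [1.0, 1.0]
        assert design.X[0, 1] == 0.0 and design.X[1, 1] == 1.0
        assert design.X[0, 2] == pytest.approx(np.log(4.0), abs=1e-12)
        assert design.y.tolist() == [1, 0]

    def test_k_minus_one_columns(self):
        schema = CovariateSchema(
            (Variable("payor", "categorical", ("A", "B", "C", "D"), "B"),), {}
        )
        table = make_cohort([{"payor": l} for l in "ABCD"], schema)
        design = encode_design_matrix(table)
        assert design.column_names == ["intercept", "payor=A", "payor=C", "payor=D"]
        # reference rows all-zero in the indicator block
        assert design.X[1, 1:].tolist() == [0.0, 0.0, 0.0]
        # each row sums to at most 1 within the block
        assert np.all(design.X[:, 1:].sum(axis=1) <= 1.0)

    def test_same_day_stay_clamped(self):
        table = make_cohort(
            [{"sex": "Female", "length_of_stay": 0.0}], self.los_schema()
        )
        assert encode_design_matrix(table).X[0, 2] == 0.0  # ln(1)

    def test_negative_los_rejected(self):
        table = make_cohort(
            [{"sex": "Female", "length_of_stay": -2.0}], self.los_schema()
        )
        with pytest.raises(ValidationError, match="negative"):
            encode_design_matrix(table)

    def test_unknown_level_rejected(self):
        table = make_cohort(
            [{"sex": "Unknown", "length_of_stay": 1.0}], self.los_schema()
        )
        with pytest.raises(ValidationError, match="sex"):
            encode_design_matrix(table)


class TestSummaries:
    def test_counts_and_percent(self, sex_schema):
        rows = [{"sex": "Female"}] * 65 + [{"sex": "Male"}] * 35
        summary = summarize_cohort(make_cohort(rows, sex_schema))
        female = summary[summary["level"] == "Female"].iloc[0]
        assert female["count"] == 65 and female["percent"] == pytest.approx(65.0)
        by_var = summary[summary["variable"] == "sex"]["percent"].sum()
        assert by_var == pytest.approx(100.0)

    def test_continuous_mean_sd(self):
        schema = CovariateSchema((Variable("x", "continuous"),), {})
        summary = summarize_cohort(
            make_cohort([{"x": v} for v in (1.0, 2.0, 3.0)], schema)
        )
        row = summary.iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(1.0)  # n-1 denominator

    def test_empty_table_rejected(self, sex_schema):
        table = make_cohort([{"sex": "Female"}], sex_schema)
        table.data = table.data.iloc[0:0]
        with pytest.raises(ValidationError):
            summarize_cohort(table)


class TestSchemaDeclarations:
    def test_reference_must_be_allowed(self):
        with pytest.raises(SchemaError):
            Variable("sex", "categorical", ("F", "M"), "X")

    def test_log_transform_continuous_only(self):
        with pytest.raises(SchemaError):
            Variable("sex", "categorical", ("F", "M"), "F", transform="log")

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "schema.yaml"
        PAYOR_SCHEMA.to_yaml(path)
        again = CovariateSchema.from_yaml(path)
        assert again.names == PAYOR_SCHEMA.names
        assert again.grouping_rules == PAYOR_SCHEMA.grouping_rules
        assert again.get("payor").reference == "Medicare traditional"
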