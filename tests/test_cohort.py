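import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfsme_costs import cohort


def _minimal_frame(rows):
    frame = pd.DataFrame(rows)
    for col in cohort.PATIENT_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    return frame[list(cohort.PATIENT_COLUMNS)]


class TestAgeBands:
    @pytest.mark.parametrize(
        "age,band",
        [(18, "18-21"), (21, "18-21"), (22, "22-29"), (29, "22-29"), (30, "30-39"),
         (39, "30-39"), (40, "40-49"), (49, "40-49"), (50, "50-59"), (59, "50-59"),
         (60, "60-64"), (64, "60-64")],
    )
    def test_band_edges_inclusive(self, age, band):
        assert cohort.assign_age_band(age) == band

    @pytest.mark.parametrize("age", [17, 65, 0, 120])
    def test_outside_eligibility_is_a_domain_error(self, age):
        with pytest.raises(ValueError):
            cohort.assign_age_band(age)

    def test_monotone_and_surjective_over_working_ages(self):
        labels = [cohort.assign_age_band(a) for a in range(18, 65)]
        order = [cohort.AGE_BAND_LABELS.index(l) for l in labels]
        assert order == sorted(order)
        assert set(labels) == set(cohort.AGE_BAND_LABELS)

    def test_vectorised_assignment_matches_scalar(self):
        ages = pd.Series(range(18, 65))
        assert list(cohort.age_band_series(ages)) == [
            cohort.assign_age_band(a) for a in ages
        ]


class TestPatientTableIO:
    def test_empty_data_section_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(cohort.PATIENT_COLUMNS) + "\n")
        frame = cohort.load_patient_table(path)
        assert len(frame) == 0
        assert cohort.records_from_frame(frame) == []

    def test_round_trip_preserves_fields_and_missing_markers(self, tmp_path):
        frame = _minimal_frame(
            [
                {"patient_id": "a", "centre": "c1", "assessment_year": 2007,
                 "age": 30, "sex": "female", "duration_illness": 24.0,
                 "employment_status": "currently_employed", "chalder_01": 2.0},
                {"patient_id": "b", "centre": "c1", "assessment_year": 2008,
                 "age": 55, "sex": "male", "duration_illness": np.nan,
                 "employment_status": None},
                {"patient_id": "c", "centre": "c2", "assessment_year": 2009,
                 "age": 41, "sex": "female", "duration_illness": 120.0,
                 "employment_status": "other", "vas": 60.0},
            ]
        )
        path = tmp_path / "t.csv"
        cohort.write_patient_table(frame, path)
        back = cohort.load_patient_table(path)
        assert len(back) == 3
        pd.testing.assert_frame_equal(back, frame, check_dtype=False)

    def test_missing_mandatory_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,age\nx,30\n")
        with pytest.raises(cohort.SchemaError, match="sex"):
            cohort.load_patient_table(path)

    def test_non_numeric_age_names_the_row(self, tmp_path):
        cols = ",".join(cohort.MANDATORY_COLUMNS)
        path = tmp_path / "bad.csv"
        path.write_text(
            f"{cols}\n"
            "a,c1,2007,30,female,10,other\n"
            "b,c1,2007,abc,male,10,other\n"
        )
        with pytest.raises(cohort.RowValidationError, match="1"):
            cohort.load_patient_table(path)

    def test_underage_record_is_excluded_and_logged(self, caplog):
        frame = _minimal_frame(
            [
                {"patient_id": "a", "centre": "c", "assessment_year": 2007,
                 "age": 17, "sex": "male", "employment_status": None},
                {"patient_id": "b", "centre": "c", "assessment_year": 2007,
                 "age": 18, "sex": "male", "employment_status": None},
            ]
        )
        with caplog.at_level(logging.INFO, logger="cfsme_costs.cohort"):
            kept = cohort.filter_eligible(frame)
        assert list(kept["patient_id"]) == ["b"]
        assert "excluded 1" in caplog.text


class TestStratify:
    def test_sex_margins_match_subtotal_counts(self):
        rng = np.random.default_rng(3)
        n_m, n_f = 501, 1669
        frame = _minimal_frame(
            [{"patient_id": str(i), "centre": "c", "assessment_year": 2007,
              "age": int(a), "sex": s, "employment_status": None}
             for i, (a, s) in enumerate(
                 [(rng.integers(18, 65), "male") for _ in range(n_m)]
                 + [(rng.integers(18, 65), "female") for _ in range(n_f)])]
        )
        strata = cohort.stratify(frame)
        assert sum(len(v) for k, v in strata.items() if k.sex == "male") == n_m
        assert sum(len(v) for k, v in strata.items() if k.sex == "female") == n_f

    def test_singleton_lands_in_exactly_one_cell(self):
        frame = _minimal_frame(
            [{"patient_id": "x", "centre": "c", "assessment_year": 2007,
              "age": 35, "sex": "female", "employment_status": None}]
        )
        strata = cohort.stratify(frame)
        nonempty = [k for k, v in strata.items() if len(v)]
        assert nonempty == [cohort.Stratum("female", "30-39")]

    def test_uniform_cohort_fills_cells_evenly(self):
        rows = []
        i = 0
        for sex in cohort.SEXES:
            for lo, hi, _ in cohort.AGE_BANDS:
                for _ in range(100):
                    rows.append(
                        {"patient_id": str(i), "centre": "c",
                         "assessment_year": 2007, "age": lo, "sex": sex,
                         "employment_status": None}
                    )
                    i += 1
        strata = cohort.stratify(_minimal_frame(rows))
        assert all(len(v) == 100 for v in strata.values())

    @settings(max_examples=25, deadline=None)
    @given(
        ages=st.lists(st.integers(18, 64), min_size=1, max_size=60),
        seed=st.integers(0, 10_000),
    )
    def test_partition_property(self, ages, seed):
        rng = np.random.default_rng(seed)
        frame = _minimal_frame(
            [{"patient_id": str(i), "centre": "c", "assessment_year": 2007,
              "age": a, "sex": rng.choice(cohort.SEXES),
              "employment_status": None}
             for i, a in enumerate(ages)]
        )
        strata = cohort.stratify(frame)
        assert sum(len(v) for v in strata.values()) == len(frame)
        seen = pd.concat([v for v in strata.values()])
        assert sorted(seen["patient_id"]) == sorted(frame["patient_id"])


class TestDomainTypes:
    def test_unknown_status_rejected(self):
        with pytest.raises(cohort.RowValidationError):
            cohort.PatientRecord("x", "c", 2007, 30, "female",
                                 employment_status="retired")

    def test_negative_duration_rejected(self):
        with pytest.raises(cohort.RowValidationError):
            cohort.PatientRecord("x", "c", 2007, 30, "male", duration_illness=-1)

    def test_external_record_allows_unemployment_exceeding_illness(self):
        rec = cohort.ExternalSampleRecord("male", 10.0, 12.0)
        assert rec.duration_unemployment == 12.0

    def test_economics_row_requires_positive_income(self):
        with pytest.raises(ValueError):
            cohort.EconomicsRow(cohort.Stratum("male", "22-29"), 0.0)

    def test_packaged_economics_covers_every_stratum(self, economics):
        assert len(economics) == 12
        rows = cohort.economics_rows(economics)
        strata = {r.stratum for r in rows}
        assert len(strata) == 12
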