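"""Domain types, validation, stratification and delimited-table I/O.

The unit of analysis is a single assessment-time record from a specialist
chronic fatigue (CFS/ME) service: demographics, self-reported duration of
illness, a four-category employment status, and item-level responses to four
patient-reported inventories. Records are held in a :class:`pandas.DataFrame`
with a fixed column schema (:data:`PATIENT_COLUMNS`); :class:`PatientRecord`
is the validated row-wise view.

Age is stratified into six bands spanning the working-age eligibility window
(18-64 inclusive); each eligible record maps to exactly one sex x age-band
stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ELIGIBLE_AGE_MIN = 18
ELIGIBLE_AGE_MAX = 64

#: Inclusive (low, high, label) age bands; they partition 18-64 exactly.
AGE_BANDS: tuple[tuple[int, int, str], ...] = (
    (18, 21, "18-21"),
    (22, 29, "22-29"),
    (30, 39, "30-39"),
    (40, 49, "40-49"),
    (50, 59, "50-59"),
    (60, 64, "60-64"),
)
AGE_BAND_LABELS: tuple[str, ...] = tuple(label for _, _, label in AGE_BANDS)
AGE_BAND_MIDPOINTS: dict[str, float] = {
    label: (lo + hi) / 2.0 for lo, hi, label in AGE_BANDS
}

SEXES = ("male", "female")

EMPLOYMENT_STATUSES = (
    "currently_employed",
    "temporarily_discontinued",
    "indefinitely_discontinued",
    "other",
)
#: Statuses pooled as the positive "discontinued employment" outcome.
DISCONTINUED_STATUSES = ("temporarily_discontinued", "indefinitely_discontinued")

CHALDER_ITEMS = tuple(f"chalder_{i:02d}" for i in range(1, 12))
SF36PF_ITEMS = tuple(f"sf36pf_{i:02d}" for i in range(1, 11))
HADS_A_ITEMS = tuple(f"hadsA_{i}" for i in range(1, 8))
HADS_D_ITEMS = tuple(f"hadsD_{i}" for i in range(1, 8))
ITEM_COLUMNS = CHALDER_ITEMS + SF36PF_ITEMS + HADS_A_ITEMS + HADS_D_ITEMS + ("vas",)

MANDATORY_COLUMNS = (
    "patient_id",
    "centre",
    "assessment_year",
    "age",
    "sex",
    "duration_illness",
    "employment_status",
)
PATIENT_COLUMNS = MANDATORY_COLUMNS + ITEM_COLUMNS


class SchemaError(ValueError):
    """A delimited table is missing mandatory columns."""


class RowValidationError(ValueError):
    """A row holds a value the schema cannot accept (reports row numbers)."""


class Stratum(NamedTuple):
    """One sex x age-band cell of the stratification."""

    sex: str
    age_band: str


@dataclass(frozen=True)
class PatientRecord:
    """One assessment-time record.

    ``employment_status`` is one of the four recorded categories or ``None``
    (unrecorded); "other" is a category in its own right, never merged with
    missing. ``duration_illness`` is months between symptom onset and
    assessment, ``None`` if unrecorded.
    """

    patient_id: str
    centre: str
    assessment_year: int
    age: int
    sex: str
    duration_illness: float | None = None
    employment_status: str | None = None
    item_responses: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RowValidationError(f"unknown sex {self.sex!r}")
        if self.employment_status is not None and (
            self.employment_status not in EMPLOYMENT_STATUSES
        ):
            raise RowValidationError(
                f"unknown employment status {self.employment_status!r}"
            )
        if self.duration_illness is not None and self.duration_illness < 0:
            raise RowValidationError("duration_illness must be >= 0")


@dataclass(frozen=True)
class EconomicsRow:
    """Per-stratum economics: mean gross annual income (GBP/year), the
    catchment (Primary Care Trust) population, and the UK population in
    thousands. Populations may be absent on bands pooled into a neighbour."""

    stratum: Stratum
    mean_annual_income: float
    pct_population: float | None = None
    uk_population_thousands: float | None = None

    def __post_init__(self) -> None:
        if self.mean_annual_income <= 0:
            raise ValueError("income must be positive")
        for v in (self.pct_population, self.uk_population_thousands):
            if v is not None and v <= 0:
                raise ValueError("populations must be positive where present")


@dataclass(frozen=True)
class ExternalSampleRecord:
    """One record of the external duration-of-unemployment sample.

    ``duration_unemployment <= duration_illness`` is deliberately not
    enforced: the source forms permit reduced hours / sick leave dates that
    predate the recorded onset of illness.
    """

    sex: str
    duration_illness: float
    duration_unemployment: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RowValidationError(f"unknown sex {self.sex!r}")
        if self.duration_illness <= 0:
            raise RowValidationError("duration_illness must be > 0")
        if self.duration_unemployment < 0:
            raise RowValidationError("duration_unemployment must be >= 0")


# ---------------------------------------------------------------------------
# age bands and stratification


def assign_age_band(age: int) -> str:
    """Return the label of the unique band containing ``age`` (edges inclusive).

    Raises ``ValueError`` outside the 18-64 eligibility window.
    """
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside eligible range 18-64")


def age_band_series(ages: pd.Series) -> pd.Series:
    """Vectorised :func:`assign_age_band` (NaN outside 18-64)."""
    edges = [lo - 0.5 for lo, _, _ in AGE_BANDS] + [AGE_BANDS[-1][1] + 0.5]
    return pd.cut(ages, bins=edges, labels=AGE_BAND_LABELS).astype(object)


def filter_eligible(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep working-age records (18 <= age <= 64); log what was excluded."""
    ok = frame["age"].between(ELIGIBLE_AGE_MIN, ELIGIBLE_AGE_MAX)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "excluded %d record(s) outside the 18-64 eligibility window (rows %s)",
            n_dropped,
            list(frame.index[~ok]),
        )
    return frame.loc[ok].copy()


def stratify(frame: pd.DataFrame) -> dict[Stratum, pd.DataFrame]:
    """Partition eligible records into the 12 sex x age-band strata.

    The result is disjoint and exhaustive: per-stratum sizes sum to the
    input size.
    """
    out: dict[Stratum, pd.DataFrame] = {}
    bands = age_band_series(frame["age"])
    if bands.isna().any():
        bad = list(frame.index[bands.isna()])
        raise ValueError(f"records outside eligibility at rows {bad}")
    for sex in SEXES:
        for label in AGE_BAND_LABELS:
            mask = (frame["sex"] == sex) & (bands == label)
            out[Stratum(sex, label)] = frame.loc[mask]
    sizes = sum(len(v) for v in out.values())
    if sizes != len(frame):
        raise ValueError("stratification is not a partition (unknown sex label?)")
    return out


# ---------------------------------------------------------------------------
# delimited-table I/O (CSV, UTF-8, header row; missing values as empty fields)


def load_patient_table(path) -> pd.DataFrame:
    """Read a patient table, one row per assessment record.

    Unparseable or empty optional fields become NaN/missing; the row count is
    preserved (eligibility filtering is a separate, logged step). Raises
    :class:`SchemaError` on missing mandatory columns and
    :class:`RowValidationError` (naming row numbers) on non-numeric ages.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "centre": str, "sex": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"patient table missing mandatory columns: {missing}")
    age = pd.to_numeric(frame["age"], errors="coerce")
    bad = frame.index[age.isna() & frame["age"].notna()]
    if len(bad):
        raise RowValidationError(f"non-numeric age at rows {list(bad)}")
    frame["age"] = age
    frame["assessment_year"] = pd.to_numeric(frame["assessment_year"], errors="coerce")
    frame["duration_illness"] = pd.to_numeric(
        frame["duration_illness"], errors="coerce"
    )
    status = frame["employment_status"].where(frame["employment_status"].notna(), None)
    unknown = set(status.dropna()) - set(EMPLOYMENT_STATUSES)
    if unknown:
        raise RowValidationError(f"unknown employment status labels: {sorted(unknown)}")
    frame["employment_status"] = status
    for col in ITEM_COLUMNS:
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
        else:
            frame[col] = np.nan
    return frame[list(PATIENT_COLUMNS)]


def write_patient_table(frame: pd.DataFrame, path) -> None:
    """Write a patient table; missing values become empty fields."""
    cols = [c for c in PATIENT_COLUMNS if c in frame.columns]
    frame.to_csv(path, index=False, columns=cols)


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    """Validated row-wise view of a patient table."""

    def _opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for _, row in frame.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                centre=str(row["centre"]),
                assessment_year=int(row["assessment_year"]),
                age=int(row["age"]),
                sex=row["sex"],
                duration_illness=_opt(row["duration_illness"]),
                employment_status=row["employment_status"]
                if isinstance(row["employment_status"], str)
                else None,
                item_responses={c: _opt(row.get(c, np.nan)) for c in ITEM_COLUMNS},
            )
        )
    return records


def _packaged(name: str):
    return resources.files("cfsme_costs.data").joinpath(name)


def load_economics_table(path=None) -> pd.DataFrame:
    """Economics table: per-stratum mean annual income (GBP), catchment (PCT)
    population and UK population (thousands). Defaults to the packaged
    published-figures fixture."""
    src = path if path is not None else _packaged("economics.csv")
    frame = pd.read_csv(src)
    required = {
        "sex",
        "age_band",
        "mean_annual_income",
        "pct_population",
        "uk_population_thousands",
    }
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"economics table missing columns: {sorted(missing)}")
    return frame


def load_cohort_summary(path=None) -> pd.DataFrame:
    """Per-stratum cohort summary (n, fraction discontinued, median illness
    duration in months). Defaults to the packaged published-figures fixture."""
    src = path if path is not None else _packaged("cohort_summary.csv")
    frame = pd.read_csv(src)
    required = {"sex", "age_band", "n", "frac_discontinued", "median_illness_months"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"cohort summary missing columns: {sorted(missing)}")
    return frame


def load_fraction_summary(path=None) -> pd.DataFrame:
    """Published per-sex unemployment-fraction summaries (mean, 95% CI, n)."""
    src = path if path is not None else _packaged("unemployment_fractions.csv")
    return pd.read_csv(src)


def load_employment_by_sex(path=None) -> pd.DataFrame:
    """Published sex x employment-status counts (employed vs discontinued)."""
    src = path if path is not None else _packaged("employment_by_sex.csv")
    return pd.read_csv(src)


def load_external_table(path) -> pd.DataFrame:
    """External-sample table: sex plus illness and unemployment durations."""
    frame = pd.read_csv(path)
    required = {"sex", "duration_illness_months", "duration_unemployment_months"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"external table missing columns: {sorted(missing)}")
    return frame


def economics_rows(frame: pd.DataFrame) -> list[EconomicsRow]:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        EconomicsRow(
            Stratum(row["sex"], row["age_band"]),
            float(row["mean_annual_income"]),
            _opt(row["pct_population"]),
            _opt(row["uk_population_thousands"]),
        )
        for _, row in frame.iterrows()
    ]
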