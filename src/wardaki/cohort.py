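"""Tabular cohort data model, CSV readers/writers and eligibility filters.

The on-disk layout is three long-format CSV files in one directory:

``admissions.csv``
    patient_id, age, sex, admit_time, discharge_time, height, weight
``measurements.csv``
    patient_id, analyte, time, value
``exposures.csv``
    patient_id, day, <one boolean column per exposure flag>

Site-specific column names can be mapped to these canonical names with a
YAML/JSON config (``column_map``).  Readers validate invariants (positive
SCr, parseable timestamps, admit < discharge) and collect row-level errors
with line numbers instead of silently dropping rows.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .egfr import compute_egfr
from .util import SchemaError, day_index

SEXES = ("female", "male")

#: canonical exposure flags, one boolean column each in exposures.csv
EXPOSURE_FLAGS = (
    "nsaid",
    "nephrotoxic_antibiotic",
    "chemotherapy",
    "vascular_imaging",
    "surgery",
    "contrast_ct",
    "icu_transfer",
)

ADMISSION_COLUMNS = ("patient_id", "age", "sex", "admit_time", "discharge_time")
MEASUREMENT_COLUMNS = ("patient_id", "analyte", "time", "value")


@dataclass
class PatientAdmission:
    """One hospital admission; readmissions are independent units."""

    patient_id: str
    age: int
    sex: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    height_cm: float | None = None
    weight_kg: float | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.sex not in SEXES and not pd.isna(self.sex):
            problems.append(f"unknown sex {self.sex!r}")
        if not pd.isna(self.age) and self.age < 0:
            problems.append("negative age")
        if self.admit_time >= self.discharge_time:
            problems.append("admit_time must precede discharge_time")
        return problems


@dataclass
class RowError:
    """A malformed input row, reported with its 1-based file line number."""

    file: str
    line: int
    message: str


@dataclass
class Cohort:
    """In-memory cohort: admissions plus long-format measurements/exposures."""

    admissions: dict[str, PatientAdmission]
    measurements: pd.DataFrame
    exposures: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.admissions)

    def series(self, patient_id: str, analyte: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for one analyte of one patient, time-sorted."""
        m = self.measurements
        sub = m[(m["patient_id"] == patient_id) & (m["analyte"] == analyte)]
        return sub["time"].to_numpy(), sub["value"].to_numpy(dtype=float)

    def scr_series(self, patient_id: str) -> tuple[np.ndarray, np.ndarray]:
        return self.series(patient_id, "SCr")

    def subset(self, patient_ids) -> "Cohort":
        keep = set(patient_ids)
        return Cohort(
            admissions={p: a for p, a in self.admissions.items() if p in keep},
            measurements=self.measurements[
                self.measurements["patient_id"].isin(keep)
            ].reset_index(drop=True),
            exposures=self.exposures[self.exposures["patient_id"].isin(keep)].reset_index(
                drop=True
            ),
        )


def _load_column_map(path: str | Path | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _rename(df: pd.DataFrame, column_map: dict, which: str) -> pd.DataFrame:
    mapping = {v: k for k, v in column_map.get(which, {}).items()}
    return df.rename(columns=mapping)


def read_cohort(
    cohort_dir: str | Path, column_map: str | Path | dict | None = None
) -> tuple[Cohort, list[RowError]]:
    """Read a cohort directory; returns the cohort and collected row errors.

    Raises SchemaError when a mandatory column is absent.  Rows with
    unparseable timestamps or invariant violations (e.g. SCr <= 0) are
    dropped from the cohort but reported in the error list with their file
    line numbers.
    """
    cohort_dir = Path(cohort_dir)
    cmap = column_map if isinstance(column_map, dict) else _load_column_map(column_map)
    errors: list[RowError] = []

    adm_raw = _rename(pd.read_csv(cohort_dir / "admissions.csv"), cmap, "admissions")
    missing = [c for c in ADMISSION_COLUMNS if c not in adm_raw.columns]
    if missing:
        raise SchemaError(f"admissions.csv missing mandatory columns: {missing}")
    admissions: dict[str, PatientAdmission] = {}
    for i, row in adm_raw.iterrows():
        line = i + 2  # header is line 1
        admit = pd.to_datetime(row["admit_time"], errors="coerce")
        disch = pd.to_datetime(row["discharge_time"], errors="coerce")
        if pd.isna(admit) or pd.isna(disch):
            errors.append(RowError("admissions.csv", line, "unparseable timestamp"))
            continue
        adm = PatientAdmission(
            patient_id=str(row["patient_id"]),
            age=row["age"] if pd.isna(row["age"]) else int(row["age"]),
            sex=row["sex"],
            admit_time=admit,
            discharge_time=disch,
            height_cm=row.get("height", np.nan),
            weight_kg=row.get("weight", np.nan),
        )
        problems = adm.validate()
        if problems:
            errors.append(RowError("admissions.csv", line, "; ".join(problems)))
            continue
        admissions[adm.patient_id] = adm

    meas_raw = _rename(pd.read_csv(cohort_dir / "measurements.csv"), cmap, "measurements")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in meas_raw.columns]
    if missing:
        raise SchemaError(f"measurements.csv missing mandatory columns: {missing}")
    meas_raw["patient_id"] = meas_raw["patient_id"].astype(str)
    times = pd.to_datetime(meas_raw["time"], errors="coerce")
    values = pd.to_numeric(meas_raw["value"], errors="coerce")
    bad_time = times.isna()
    bad_value = values.isna()
    bad_scr = (meas_raw["analyte"] == "SCr") & (values <= 0)
    for i in meas_raw.index[bad_time]:
        errors.append(RowError("measurements.csv", i + 2, "unparseable timestamp"))
    for i in meas_raw.index[bad_value & ~bad_time]:
        errors.append(RowError("measurements.csv", i + 2, "non-numeric value"))
    for i in meas_raw.index[bad_scr]:
        errors.append(
            RowError("measurements.csv", i + 2, f"SCr must be > 0, got {values[i]}")
        )
    keep = ~(bad_time | bad_value | bad_scr)
    measurements = pd.DataFrame(
        {
            "patient_id": meas_raw.loc[keep, "patient_id"],
            "analyte": meas_raw.loc[keep, "analyte"],
            "time": times[keep],
            "value": values[keep],
        }
    )
    measurements = measurements.sort_values(
        ["patient_id", "analyte", "time"], kind="stable"
    ).reset_index(drop=True)

    exp_path = cohort_dir / "exposures.csv"
    if exp_path.exists():
        exposures = _rename(pd.read_csv(exp_path), cmap, "exposures")
        if "patient_id" not in exposures.columns or "day" not in exposures.columns:
            raise SchemaError("exposures.csv missing patient_id/day columns")
        exposures["patient_id"] = exposures["patient_id"].astype(str)
        exposures["day"] = pd.to_datetime(exposures["day"]).dt.normalize()
        for flag in EXPOSURE_FLAGS:
            if flag not in exposures.columns:
                exposures[flag] = False
            exposures[flag] = exposures[flag].astype(bool)
    else:
        exposures = pd.DataFrame(
            columns=["patient_id", "day", *EXPOSURE_FLAGS]
        ).astype({flag: bool for flag in EXPOSURE_FLAGS})

    return Cohort(admissions, measurements, exposures), errors


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write the three canonical CSV files; inverse of read_cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for adm in cohort.admissions.values():
        rows.append(
            {
                "patient_id": adm.patient_id,
                "age": adm.age,
                "sex": adm.sex,
                "admit_time": adm.admit_time.isoformat(),
                "discharge_time": adm.discharge_time.isoformat(),
                "height": adm.height_cm,
                "weight": adm.weight_kg,
            }
        )
    pd.DataFrame(rows, columns=["patient_id", "age", "sex", "admit_time",
                                "discharge_time", "height", "weight"]).to_csv(
        out_dir / "admissions.csv", index=False
    )
    meas = cohort.measurements.copy()
    meas["time"] = meas["time"].map(lambda t: t.isoformat())
    meas.to_csv(out_dir / "measurements.csv", index=False, float_format="%.6g")
    exp = cohort.exposures.copy()
    if len(exp):
        exp["day"] = exp["day"].dt.strftime("%Y-%m-%d")
    exp.to_csv(out_dir / "exposures.csv", index=False)


# ---------------------------------------------------------------------------
# Eligibility filtering
# ---------------------------------------------------------------------------

#: exclusion rules in the order they are applied; a patient is attributed to
#: the first rule that fires
ELIGIBILITY_RULES = (
    "unevaluable",       # missing age or sex: eGFR screen impossible
    "age_lt_19",
    "scr_lt_3",
    "egfr_le_60_first_day",
    "day1_aki",
)


@dataclass
class CohortFilterReport:
    """Counts of patients excluded per rule; reconciles with the input size."""

    total: int
    excluded: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.retained + sum(self.excluded.values()) == self.total

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {k: v for k, v in dataclasses.asdict(self).items() if k != "excluded_ids"},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_eligibility(cohort: Cohort, egfr_cut: float = 60.0, min_scr: int = 3,
                      min_age: int = 19) -> tuple[Cohort, CohortFilterReport]:
    """Apply the cohort eligibility rules and return (filtered, report).

    Rules, applied in order: adults only (age >= 19); at least ``min_scr``
    SCr measurements during the stay; eGFR > ``egfr_cut`` on the first day
    of SCr measurement (first chronological SCr of that calendar day); no
    AKI onset (refined definition) on admission day 1, since at least one
    prior day of data is needed for prediction.  Patients with missing age
    or sex cannot be screened and land in an "unevaluable" bucket.

    Idempotent: re-applying to the filtered cohort excludes no one.
    """
    from .labeler import LabelParams, detect_aki_refined

    report = CohortFilterReport(total=len(cohort.admissions))
    report.excluded = {rule: 0 for rule in ELIGIBILITY_RULES}
    report.excluded_ids = {rule: [] for rule in ELIGIBILITY_RULES}
    params = LabelParams()
    keep: list[str] = []

    for pid, adm in cohort.admissions.items():
        times, values = cohort.scr_series(pid)

        def _exclude(rule: str) -> None:
            report.excluded[rule] += 1
            report.excluded_ids[rule].append(pid)

        if pd.isna(adm.age) or adm.sex not in SEXES:
            _exclude("unevaluable")
            continue
        if adm.age < min_age:
            _exclude("age_lt_19")
            continue
        if len(values) < min_scr:
            _exclude("scr_lt_3")
            continue
        first_day = pd.Timestamp(times[0]).normalize()
        same_day = times < (first_day + pd.Timedelta(days=1)).to_datetime64()
        first_scr = values[same_day][0]  # first chronological SCr that day
        if compute_egfr(first_scr, adm.age, adm.sex) <= egfr_cut:
            _exclude("egfr_le_60_first_day")
            continue
        event, _ = detect_aki_refined(times, values, adm.admit_time, params, pid)
        if event is not None and day_index(event.onset_time, adm.admit_time) == 1:
            _exclude("day1_aki")
            continue
        keep.append(pid)

    report.retained = len(keep)
    return cohort.subset(keep), report
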