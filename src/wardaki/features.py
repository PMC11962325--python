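"""Per-day feature engineering for the prediction models.

Raw ward records are irregular; models see one row per patient-day:

* vitals — mean/max/min and measurement count over the calendar day;
* labs — most recent value at or before the end of the day (carried
  forward within the admission), plus a delta feature: current value minus
  the median of the previous observed values of that analyte;
* derived — CKD-EPI 2021 eGFR and the BUN/Cr ratio;
* exposures — nephrotoxic drug classes, surgery, contrast CT, vascular
  imaging, ICU transfer, each true when it occurred in the trailing 7 days
  (index day included);
* demographics — age, sex, BMI.

Every lab cell carries a provenance state (observed / carried-forward /
imputed / missing-level).  Missing-data handling is two-stage and fitted on
the training split only: carry-forward first, then chained-equation
imputation for features with residual missingness below 20%, or conversion
to quantile categories with an explicit "missing" level above it.  Robust
scaling (median/IQR of the training split) finishes the pipeline; its state
serializes to JSON bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EXPOSURE_FLAGS, Cohort
from .egfr import compute_egfr
from .util import PipelineError, day_index

#: provenance states for lab-derived cells
PROVENANCE = ("observed", "carried", "imputed", "missing_level", "missing")

DEFAULT_VITALS = ("heart_rate", "sbp", "dbp", "body_temp", "resp_rate")
DEFAULT_LABS = (
    "SCr", "BUN", "hemoglobin", "albumin", "platelet", "WBC", "CRP",
    "aPTT", "total_bilirubin", "sodium", "chloride", "calcium", "glucose",
    "pH", "total_co2", "urine_sg", "ALT", "ALP",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Which analytes enter the table and how exposures are windowed."""

    vitals: tuple[str, ...] = DEFAULT_VITALS
    labs: tuple[str, ...] = DEFAULT_LABS
    delta_labs: tuple[str, ...] = ("SCr", "BUN", "hemoglobin", "platelet", "WBC")
    exposure_window_days: int = 7
    # physiologic clipping ranges; values outside are treated as outliers
    clip: dict = field(default_factory=dict)


def compute_delta(history, current) -> float:
    """Current value minus the median of the previous observed values."""
    hist = np.asarray(history, dtype=float)
    if hist.size == 0:
        return np.nan
    return float(current - np.median(hist))


def summarize_days(cohort: Cohort, config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """One feature row per in-hospital patient-day.

    Lab provenance is recorded in ``<lab>_src`` companion columns.
    Negative vital values are rejected (physiologically impossible).
    """
    m = cohort.measurements
    vit = m[m["analyte"].isin(config.vitals)]
    if (vit["value"] < 0).any():
        raise ValueError("negative vital sign values in input")
    # admission-day index per measurement, computed once
    admit_days = m["patient_id"].map(
        {pid: a.admit_time.normalize() for pid, a in cohort.admissions.items()}
    )
    mday = (m["time"].dt.normalize() - admit_days).dt.days + 1
    # (patient, analyte) -> (sorted day indices, values)
    arrays: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (pid, analyte), sub in m.groupby(["patient_id", "analyte"], sort=False):
        arrays[(pid, analyte)] = (
            mday[sub.index].to_numpy(dtype=int),
            sub["value"].to_numpy(dtype=float),
        )
    empty = (np.empty(0, dtype=int), np.empty(0))
    rows = []
    for pid, adm in cohort.admissions.items():
        los = day_index(adm.discharge_time, adm.admit_time)
        exp = cohort.exposures[cohort.exposures["patient_id"] == pid]
        exp_days = {
            flag: {day_index(d, adm.admit_time) for d in exp.loc[exp[flag], "day"]}
            for flag in EXPOSURE_FLAGS
        }
        bmi = np.nan
        if not pd.isna(adm.height_cm) and not pd.isna(adm.weight_kg) and adm.height_cm > 0:
            bmi = adm.weight_kg / (adm.height_cm / 100.0) ** 2
        for d in range(1, los + 1):
            row = {"patient_id": pid, "day": d, "age": adm.age,
                   "sex_female": 1.0 if adm.sex == "female" else 0.0, "bmi": bmi}
            for v in config.vitals:
                days, vals = arrays.get((pid, v), empty)
                sel = vals[days == d]
                row[f"{v}_count"] = float(len(sel))
                row[f"{v}_mean"] = sel.mean() if len(sel) else np.nan
                row[f"{v}_max"] = sel.max() if len(sel) else np.nan
                row[f"{v}_min"] = sel.min() if len(sel) else np.nan
            for lab in config.labs:
                days, vals = arrays.get((pid, lab), empty)
                start = np.searchsorted(days, d, side="left")
                stop = np.searchsorted(days, d, side="right")
                before = vals[:start]
                if stop > start:
                    row[lab] = float(vals[stop - 1])
                    row[f"{lab}_src"] = "observed"
                elif start > 0:
                    row[lab] = float(before[-1])
                    row[f"{lab}_src"] = "carried"
                else:
                    row[lab] = np.nan
                    row[f"{lab}_src"] = "missing"
                if lab in config.delta_labs:
                    row[f"{lab}_delta"] = (
                        compute_delta(before, row[lab]) if not np.isnan(row[lab])
                        else np.nan
                    )
            scr = row.get("SCr", np.nan)
            row["egfr"] = (
                compute_egfr(scr, adm.age, adm.sex)
                if not np.isnan(scr) and adm.sex in ("female", "male") else np.nan
            )
            bun = row.get("BUN", np.nan)
            row["bun_cr_ratio"] = bun / scr if not (np.isnan(bun) or np.isnan(scr)) else np.nan
            for flag in EXPOSURE_FLAGS:
                w = config.exposure_window_days
                row[f"exp_{flag}"] = float(
                    any(d - w + 1 <= e <= d for e in exp_days[flag])
                )
            rows.append(row)
    df = pd.DataFrame(rows)
    for col, (lo, hi) in config.clip.items():
        if col in df.columns:
            df[col] = df[col].clip(lo, hi)
    return df


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute(
    table: pd.DataFrame,
    feature_cols: list[str],
    train_mask: np.ndarray,
    threshold: float = 0.2,
    seed: int = 0,
    max_iter: int = 10,
    n_bins: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Two-stage missing-data handling fitted on the training rows only.

    Features with training-split missingness below ``threshold`` are
    imputed with chained equations (round-robin linear regressions, fixed
    iteration count, seeded).  Features at or above it become quantile
    categories (``n_bins`` training-quantile groups) one-hot encoded with
    an explicit missing level.  Returns the transformed table and a policy
    dict recording each feature's treatment; provenance (``_src``) columns
    are updated to ``imputed`` / ``missing_level`` where cells were filled.

    Raises PipelineError when the training mask selects no rows (fitting
    on the evaluation split would leak).
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() == 0:
        raise PipelineError("empty training mask: refusing to fit on evaluation rows")
    out = table.copy()
    miss = out.loc[train_mask, feature_cols].isna().mean()
    numeric = [c for c in feature_cols if miss[c] < threshold]
    categorical = [c for c in feature_cols if miss[c] >= threshold]
    policy: dict = {"numeric": numeric, "categorical": {}, "threshold": threshold}

    if numeric:
        imputer = IterativeImputer(max_iter=max_iter, random_state=seed,
                                   sample_posterior=False, keep_empty_features=True)
        imputer.fit(out.loc[train_mask, numeric])
        was_na = out[numeric].isna()
        filled = imputer.transform(out[numeric])
        out[numeric] = filled
        for c in numeric:
            src = f"{c}_src"
            if src in out.columns:
                out.loc[was_na[c], src] = "imputed"

    for c in categorical:
        train_vals = out.loc[train_mask, c].dropna()
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = np.unique(np.quantile(train_vals, qs)) if len(train_vals) else np.array([])
        codes = np.digitize(out[c].to_numpy(dtype=float), edges)  # NaN -> last+? guard:
        is_na = out[c].isna().to_numpy()
        for b in range(len(edges) + 1):
            out[f"{c}__bin{b}"] = ((codes == b) & ~is_na).astype(float)
        out[f"{c}__missing"] = is_na.astype(float)
        src = f"{c}_src"
        if src in out.columns:
            out.loc[is_na, src] = "missing_level"
        policy["categorical"][c] = edges.tolist()
        out = out.drop(columns=[c])
    return out, policy


# ---------------------------------------------------------------------------
# Robust scaling
# ---------------------------------------------------------------------------

@dataclass
class ScalerState:
    """Per-feature median/IQR learned on a training split; JSON-round-trippable."""

    medians: dict[str, float]
    iqrs: dict[str, float]
    constant: list[str]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"medians": self.medians, "iqrs": self.iqrs, "constant": self.constant}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ScalerState":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(d["medians"], d["iqrs"], d["constant"])

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c, med in self.medians.items():
            if c in self.constant or c not in out.columns:
                continue
            out[c] = (out[c] - med) / self.iqrs[c]
        return out


def fit_apply_scaler(
    train: pd.DataFrame, *others: pd.DataFrame, feature_cols: list[str] | None = None
) -> tuple[list[pd.DataFrame], ScalerState]:
    """Fit a median/IQR scaler on ``train`` and apply it everywhere.

    Constant features (IQR 0) are flagged and passed through unscaled.
    """
    if len(train) == 0:
        raise PipelineError("empty training table")
    cols = feature_cols or [
        c for c in train.columns
        if train[c].dtype.kind in "fi" and c not in ("day",)
        and not c.endswith("_src") and c != "patient_id"
    ]
    medians, iqrs, constant = {}, {}, []
    for c in cols:
        med = float(train[c].median())
        q1, q3 = train[c].quantile(0.25), train[c].quantile(0.75)
        iqr = float(q3 - q1)
        medians[c] = med
        if iqr == 0 or np.isnan(iqr):
            constant.append(c)
            iqrs[c] = 1.0
        else:
            iqrs[c] = iqr
    state = ScalerState(medians, iqrs, constant)
    return [state.transform(t) for t in (train, *others)], state
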