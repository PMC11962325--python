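"""Baseline SCr estimation and AKI detection (standard and refined KDIGO).

Standard KDIGO creatinine criteria call a measurement AKI when it rises
>= 0.3 mg/dL above the minimum of the previous 48 h, or reaches >= 1.5x the
minimum of the previous 7 days.  On general wards, where many patients have
low, fluctuating creatinine, the relative rule misfires: a patient measuring
0.9 -> 0.6 -> 0.9 mg/dL within 48 h is "AKI" purely because of a transient
dip, and baselines below 0.6 mg/dL let trivial fluctuations cross the 1.5x
bar.

The refined definition implemented here counters both failure modes:

* the baseline is the lowest SCr of the previous 7 days, but a candidate
  minimum that sits >= 0.3 mg/dL below BOTH the median of the other window
  values and the most recent window value is excluded as a transient dip
  (cascading to the next-lowest candidate; if every candidate is excluded
  the window median serves as baseline);
* a minimum absolute increase of 0.3 mg/dL over that baseline is always
  required; the 1.5x ratio is additionally required when the baseline
  measurement is older than 48 h.

Both detectors return at most one event per admission (the first onset).
All thresholds are inclusive (>=) with a small float tolerance; windows are
half-open and never contain the measurement under evaluation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .util import day_index


@dataclass(frozen=True)
class LabelParams:
    """Thresholds of the AKI/AKD definitions, in the unit of the SCr series.

    Defaults are the mg/dL values; `scaled` converts to another unit
    (e.g. `scaled(88.4)` for µmol/L).
    """

    window_days: float = 7.0
    abs_window_hours: float = 48.0
    min_increase: float = 0.3
    ratio: float = 1.5
    exclusion_delta: float = 0.3
    low_baseline_cut: float = 0.6
    tol: float = 1e-9

    def scaled(self, factor: float) -> "LabelParams":
        return replace(
            self,
            min_increase=self.min_increase * factor,
            exclusion_delta=self.exclusion_delta * factor,
            low_baseline_cut=self.low_baseline_cut * factor,
            tol=self.tol * factor,
        )


@dataclass
class BaselineEstimate:
    """Baseline SCr at one evaluation time, with a full audit trail."""

    eval_time: pd.Timestamp
    value: float
    baseline_time: pd.Timestamp | None  # None when reason == "all_excluded"
    excluded: list[tuple[pd.Timestamp, float, str]] = field(default_factory=list)
    window_values: np.ndarray | None = None
    reason: str = "min_window"  # or "all_excluded"


@dataclass
class AkiEvent:
    patient_id: str
    onset_time: pd.Timestamp
    onset_day: int
    onset_scr: float
    baseline_value: float
    baseline_time: pd.Timestamp | None
    criteria: dict
    definition: str  # "standard" | "refined"
    baseline: BaselineEstimate | None = None


@dataclass
class AuditRow:
    """One refined-criteria evaluation (one SCr measurement)."""

    time: pd.Timestamp
    value: float
    baseline_value: float | None
    baseline_time: pd.Timestamp | None
    baseline_reason: str | None
    n_excluded: int
    delta: float | None
    fired: bool
    skip_reason: str | None = None


def _as_dt64(times) -> np.ndarray:
    return pd.to_datetime(np.asarray(times)).to_numpy(dtype="datetime64[ns]")


def _td(hours: float) -> np.timedelta64:
    return np.timedelta64(int(round(hours * 3600 * 1e9)), "ns")


def estimate_baseline_refined(
    times, values, eval_time, params: LabelParams = LabelParams()
) -> BaselineEstimate | None:
    """Baseline SCr at ``eval_time`` under the refined rule.

    Window: measurements strictly within the 7 days before ``eval_time``
    (the measurement at ``eval_time`` itself is never its own baseline).
    Candidates are tested lowest-first; a candidate is excluded when it is
    >= ``exclusion_delta`` below both the median of the other window values
    and the most recent other window value.  Returns None when the window
    is empty — the caller must skip the evaluation, never default to 0.
    """
    t_arr = _as_dt64(times)
    v_arr = np.asarray(values, dtype=float)
    t0 = pd.Timestamp(eval_time).to_datetime64()
    mask = (t_arr > t0 - _td(params.window_days * 24)) & (t_arr < t0)
    if not mask.any():
        return None
    wt, wv = t_arr[mask], v_arr[mask]
    excluded: list[tuple[pd.Timestamp, float, str]] = []
    # lowest value first; earlier measurement wins a value tie
    order = np.lexsort((wt, wv))
    for idx in order:
        cand_v = wv[idx]
        others = np.ones(len(wv), dtype=bool)
        others[idx] = False
        if not others.any():  # singleton window: nothing to compare against
            return BaselineEstimate(
                pd.Timestamp(t0), float(cand_v), pd.Timestamp(wt[idx]),
                excluded, wv, "min_window",
            )
        med = float(np.median(wv[others]))
        recent = float(wv[others][np.argmax(wt[others])])
        below_median = med - cand_v >= params.exclusion_delta - params.tol
        below_recent = recent - cand_v >= params.exclusion_delta - params.tol
        if below_median and below_recent:
            excluded.append(
                (
                    pd.Timestamp(wt[idx]),
                    float(cand_v),
                    f"ge_{params.exclusion_delta:g}_below_median_and_recent",
                )
            )
            continue
        return BaselineEstimate(
            pd.Timestamp(t0), float(cand_v), pd.Timestamp(wt[idx]),
            excluded, wv, "min_window",
        )
    # every candidate looked like a transient dip: fall back to window median
    return BaselineEstimate(
        pd.Timestamp(t0), float(np.median(wv)), None, excluded, wv, "all_excluded"
    )


def standard_flags_at(t_arr, v_arr, i: int, params: LabelParams) -> dict:
    """Standard-KDIGO criterion flags for measurement ``i`` of a series."""
    t, v = t_arr[i], v_arr[i]
    out = {"abs48h": False, "rel7d": False, "baseline_value": None,
           "baseline_time": None}
    prior48 = (t_arr > t - _td(params.abs_window_hours)) & (t_arr < t)
    prior7d = (t_arr > t - _td(params.window_days * 24)) & (t_arr < t)
    min48 = min7 = None
    if prior48.any():
        j = np.where(prior48)[0][np.argmin(v_arr[prior48])]
        min48 = v_arr[j]
        if v - min48 >= params.min_increase - params.tol:
            out["abs48h"] = True
            out["baseline_value"], out["baseline_time"] = float(min48), pd.Timestamp(t_arr[j])
    if prior7d.any():
        j = np.where(prior7d)[0][np.argmin(v_arr[prior7d])]
        min7 = v_arr[j]
        if v >= params.ratio * min7 - params.tol:
            out["rel7d"] = True
            # the relative rule's baseline (the 7-day minimum) takes
            # precedence for the low-baseline subclassification
            out["baseline_value"], out["baseline_time"] = float(min7), pd.Timestamp(t_arr[j])
    return out


def detect_aki_standard(
    times, values, admit_time, params: LabelParams = LabelParams(),
    patient_id: str = "",
) -> AkiEvent | None:
    """First AKI onset under the standard KDIGO creatinine criteria."""
    t_arr = _as_dt64(times)
    v_arr = np.asarray(values, dtype=float)
    if len(v_arr) == 0:
        raise ValueError("empty SCr series")
    for i in range(len(v_arr)):
        flags = standard_flags_at(t_arr, v_arr, i, params)
        if flags["abs48h"] or flags["rel7d"]:
            onset = pd.Timestamp(t_arr[i])
            return AkiEvent(
                patient_id=patient_id,
                onset_time=onset,
                onset_day=day_index(onset, admit_time),
                onset_scr=float(v_arr[i]),
                baseline_value=flags["baseline_value"],
                baseline_time=flags["baseline_time"],
                criteria={"abs48h": flags["abs48h"], "rel7d": flags["rel7d"],
                          "min_increase": v_arr[i] - flags["baseline_value"]
                          >= params.min_increase - params.tol},
                definition="standard",
            )
    return None


def detect_aki_refined(
    times, values, admit_time, params: LabelParams = LabelParams(),
    patient_id: str = "",
) -> tuple[AkiEvent | None, list[AuditRow]]:
    """First AKI onset under the refined criteria, plus a per-evaluation audit.

    A measurement fires when it exceeds the exclusion-filtered baseline by
    >= ``min_increase`` AND (the baseline measurement lies within the
    previous 48 h OR the value reaches ``ratio`` x baseline).  Evaluations
    without any baseline window are skipped and recorded in the audit.
    """
    t_arr = _as_dt64(times)
    v_arr = np.asarray(values, dtype=float)
    if len(v_arr) == 0:
        raise ValueError("empty SCr series")
    audit: list[AuditRow] = []
    for i in range(len(v_arr)):
        t, v = pd.Timestamp(t_arr[i]), float(v_arr[i])
        est = estimate_baseline_refined(t_arr, v_arr, t, params)
        if est is None:
            audit.append(AuditRow(t, v, None, None, None, 0, None, False,
                                  skip_reason="no_window"))
            continue
        delta = v - est.value
        min_inc = delta >= params.min_increase - params.tol
        within48 = est.baseline_time is not None and (
            t.to_datetime64() - est.baseline_time.to_datetime64()
            <= _td(params.abs_window_hours)
        )
        rel = v >= params.ratio * est.value - params.tol
        fired = min_inc and (within48 or rel)
        audit.append(
            AuditRow(t, v, est.value, est.baseline_time, est.reason,
                     len(est.excluded), delta, fired)
        )
        if fired:
            return (
                AkiEvent(
                    patient_id=patient_id,
                    onset_time=t,
                    onset_day=day_index(t, admit_time),
                    onset_scr=v,
                    baseline_value=est.value,
                    baseline_time=est.baseline_time,
                    criteria={"abs48h": within48, "rel7d": rel, "min_increase": min_inc},
                    definition="refined",
                    baseline=est,
                ),
                audit,
            )
    return None, audit


def is_ambiguous(times, values, params: LabelParams = LabelParams()) -> bool:
    """True when AKI labeling for this series is ambiguous.

    A series is ambiguous when some measurement fires the standard criteria
    while the refined baseline there is unusable (empty window or every
    candidate excluded), and no unambiguous refined onset occurs at or
    before the end of the series.  Such patients are dropped from the
    prediction tasks with an audit reason.
    """
    t_arr = _as_dt64(times)
    v_arr = np.asarray(values, dtype=float)
    saw_unusable_candidate = False
    for i in range(len(v_arr)):
        flags = standard_flags_at(t_arr, v_arr, i, params)
        est = estimate_baseline_refined(t_arr, v_arr, pd.Timestamp(t_arr[i]), params)
        if est is not None and est.reason == "min_window":
            delta = v_arr[i] - est.value
            within48 = est.baseline_time is not None and (
                t_arr[i] - est.baseline_time.to_datetime64()
                <= _td(params.abs_window_hours)
            )
            if (delta >= params.min_increase - params.tol
                    and (within48 or v_arr[i] >= params.ratio * est.value - params.tol)):
                return False  # unambiguous refined onset found first
        if (flags["abs48h"] or flags["rel7d"]) and (
            est is None or est.reason == "all_excluded"
        ):
            saw_unusable_candidate = True
    return saw_unusable_candidate


# ---------------------------------------------------------------------------
# Criteria comparison
# ---------------------------------------------------------------------------

@dataclass
class CriteriaComparison:
    """Per-patient standard-vs-refined classification and summary counts."""

    rows: pd.DataFrame  # patient_id, category, subclass
    counts: dict

    def summary(self) -> dict:
        from .util import percent

        c = dict(self.counts)
        if c["standard_only"]:
            c["low_baseline_pct_of_standard_only"] = percent(
                c["low_baseline"], c["standard_only"], 2
            )
        return c


def compare_criteria(
    patients, params: LabelParams = LabelParams()
) -> CriteriaComparison:
    """Classify each patient by which AKI definitions they satisfy.

    ``patients`` yields (patient_id, times, values, admit_time).  Patients
    with a standard event but no refined event ("standard_only", the cases
    the refined definition declassifies) are subclassified:

    * ``low_baseline`` — the standard-onset baseline was < 0.6 mg/dL;
    * ``pre_onset_decrease`` — the refined baseline exclusion fired at the
      standard onset time (a transient dip preceded the apparent rise);
    * ``other`` — anything else.
    """
    recs = []
    for pid, times, values, admit_time in patients:
        std = detect_aki_standard(times, values, admit_time, params, pid)
        ref, _ = detect_aki_refined(times, values, admit_time, params, pid)
        if ref is not None:
            cat, sub = "refined", ""
        elif std is not None:
            cat = "standard_only"
            if std.baseline_value < params.low_baseline_cut - params.tol:
                sub = "low_baseline"
            else:
                est = estimate_baseline_refined(times, values, std.onset_time, params)
                sub = (
                    "pre_onset_decrease"
                    if est is not None and len(est.excluded) > 0
                    else "other"
                )
        else:
            cat, sub = "neither", ""
        recs.append({"patient_id": pid, "category": cat, "subclass": sub})
    rows = pd.DataFrame(recs, columns=["patient_id", "category", "subclass"])
    counts = {
        "n": len(rows),
        "refined": int((rows["category"] == "refined").sum()),
        "standard_only": int((rows["category"] == "standard_only").sum()),
        "neither": int((rows["category"] == "neither").sum()),
        "low_baseline": int((rows["subclass"] == "low_baseline").sum()),
        "pre_onset_decrease": int((rows["subclass"] == "pre_onset_decrease").sum()),
        "other": int((rows["subclass"] == "other").sum()),
    }
    counts["standard"] = counts["refined"] + counts["standard_only"]
    return CriteriaComparison(rows, counts)
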