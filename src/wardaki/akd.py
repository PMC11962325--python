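"""AKD recovery adjudication and day-level labels for the prediction tasks.

AKD (acute kidney disease) is the persistence of AKI: the patient's SCr
does not return below 1.5x the onset-time baseline within 7 days of onset.
Adjudication needs post-onset measurements; with too few, the outcome is
``indeterminate`` — a value, not an error — and the patient is excluded
from the AKD task.

Two label tables feed the models:

* AKI task — one row per in-hospital patient-day; days 1-3 before a
  (refined) AKI onset are labeled 1, the onset day and everything after it
  is excluded, remaining days are 0.  Days whose next 7 calendar days
  contain no SCr measurement are excluded (the onset could not have been
  observed there), and patients with ambiguous labeling are dropped whole.
* AKD task — one row per AKI patient at the onset day; 1 = progressed to
  AKD, 0 = recovered, indeterminate rows are excluded.

Label tables are long-format DataFrames with columns (patient_id, day,
label, reason) where label is 1, 0 or -1 (excluded; reason says why).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .labeler import AkiEvent, LabelParams, detect_aki_refined, is_ambiguous
from .util import PipelineError, day_index

EXCLUDED = -1


@dataclass(frozen=True)
class AkdParams:
    recovery_window_days: int = 7
    min_post_scr: int = 1
    late_window: tuple[int, int] = (5, 7)  # days that can rule out late recovery


@dataclass
class AkdOutcome:
    patient_id: str
    event: AkiEvent
    status: str  # {"recovered", "akd", "indeterminate"}
    recovery_time: pd.Timestamp | None
    post_onset_scr_count: int


def assess_akd(
    times, values, event: AkiEvent, admit_time,
    params: AkdParams = AkdParams(), tol: float = 1e-9,
) -> AkdOutcome:
    """Adjudicate recovery vs AKD for one AKI event.

    Scans SCr measurements after onset, up to ``recovery_window_days``
    calendar days past the onset day.  The first value strictly below
    1.5x the onset-time baseline (frozen; a moving baseline would make
    recovery ill-defined) marks recovery.  Without one, the outcome is AKD
    only when the window holds >= ``min_post_scr`` measurements including
    at least one in the late window (days 5-7 by default) — otherwise a
    late recovery cannot be ruled out and the outcome is indeterminate.
    """
    threshold = 1.5 * event.baseline_value
    onset_day = day_index(event.onset_time, admit_time)
    post = []
    for t, v in zip(pd.to_datetime(pd.Series(list(times))), values):
        rel = day_index(t, admit_time) - onset_day
        if t > event.onset_time and 0 <= rel <= params.recovery_window_days:
            post.append((t, float(v), rel))
    for t, v, _rel in post:
        if threshold - v > tol:  # strictly below 1.5x baseline
            return AkdOutcome(event.patient_id, event, "recovered", t, len(post))
    lo, hi = params.late_window
    has_late = any(lo <= rel <= hi for _t, _v, rel in post)
    if len(post) >= params.min_post_scr and has_late:
        return AkdOutcome(event.patient_id, event, "akd", None, len(post))
    return AkdOutcome(event.patient_id, event, "indeterminate", None, len(post))


def label_cohort(
    cohort: Cohort, params: LabelParams = LabelParams()
) -> tuple[dict[str, AkiEvent], dict[str, str]]:
    """Run the refined detector on every patient.

    Returns (events by patient, dropped patients with reason).  Patients
    whose labeling is ambiguous (a standard-criteria onset with no usable
    refined baseline and no clean refined onset) are dropped.
    """
    events: dict[str, AkiEvent] = {}
    dropped: dict[str, str] = {}
    for pid, adm in cohort.admissions.items():
        times, values = cohort.scr_series(pid)
        if len(values) == 0:
            dropped[pid] = "no_scr"
            continue
        if is_ambiguous(times, values, params):
            dropped[pid] = "ambiguous_aki_labeling"
            continue
        event, _audit = detect_aki_refined(times, values, adm.admit_time, params, pid)
        if event is not None:
            events[pid] = event
    return events, dropped


def build_aki_day_labels(
    cohort: Cohort,
    events: dict[str, AkiEvent],
    dropped: dict[str, str] | None = None,
    horizon_days: int = 3,
    lookahead_days: int = 7,
) -> pd.DataFrame:
    """Day-level labels for the early-AKI task.

    For AKI patients, days ``onset-horizon`` … ``onset-1`` are labeled 1
    and the onset day onward is excluded; all other in-hospital days are 0.
    Any day with no SCr measurement in its next ``lookahead_days`` calendar
    days (index day included) is excluded, taking precedence over a 0/1
    label.  Exclusion reasons are mutually exclusive per day.
    """
    dropped = dropped or {}
    recs = []
    for pid, adm in cohort.admissions.items():
        if pid in dropped:
            continue
        los = day_index(adm.discharge_time, adm.admit_time)
        times, _values = cohort.scr_series(pid)
        scr_days = {day_index(t, adm.admit_time) for t in times}
        onset_day = events[pid].onset_day if pid in events else None
        for d in range(1, los + 1):
            has_lookahead = any(d <= s <= d + lookahead_days - 1 for s in scr_days)
            if onset_day is not None and d >= onset_day:
                label, reason = EXCLUDED, ("onset_day" if d == onset_day else "post_onset")
            elif not has_lookahead:
                label, reason = EXCLUDED, "no_scr_lookahead"
            elif onset_day is not None and onset_day - horizon_days <= d <= onset_day - 1:
                label, reason = 1, ""
            else:
                label, reason = 0, ""
            recs.append({"patient_id": pid, "day": d, "label": label, "reason": reason})
    return pd.DataFrame(recs, columns=["patient_id", "day", "label", "reason"])


def build_akd_labels(
    events: dict[str, AkiEvent], outcomes: dict[str, AkdOutcome]
) -> pd.DataFrame:
    """Onset-day labels for the AKD task (1 = AKD, 0 = recovered)."""
    recs = []
    for pid, event in events.items():
        if pid not in outcomes:
            raise PipelineError(f"AKI event for {pid} has no AKD outcome; "
                                "assess_akd must run before build_akd_labels")
        status = outcomes[pid].status
        if status == "akd":
            label, reason = 1, ""
        elif status == "recovered":
            label, reason = 0, ""
        else:
            label, reason = EXCLUDED, "indeterminate_akd"
        recs.append({"patient_id": pid, "day": event.onset_day,
                     "label": label, "reason": reason})
    return pd.DataFrame(recs, columns=["patient_id", "day", "label", "reason"])
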