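"""Synthetic general-ward cohorts with known AKI/AKD ground truth.

No public ward EHR with AKI adjudication exists, so every pipeline stage is
exercised on simulated admissions whose event labels are known by
construction.  Trajectories are piecewise processes on calendar days:

* a stable per-patient baseline SCr (sex-specific) with Gaussian jitter;
* true AKI — a rise at onset reaching at least max(1.5x baseline,
  baseline + 0.3 mg/dL) plus a margin, followed by exponential-style decay
  back below 1.5x baseline within 7 days (recoverers) or a plateau that
  stays above it (AKD);
* transient fluctuations engineered to fool the standard KDIGO criteria
  but not the refined ones: low-baseline (< 0.6 mg/dL) patients whose
  one-day bump crosses 1.5x the window minimum while staying < 0.3 mg/dL
  above it, and normal-baseline patients with a one-day dip >= 0.3 mg/dL
  followed by return to baseline;
* optional day-1 onsets (several same-day measurements), used to exercise
  the admission-day eligibility exclusion.

Measurement sparsity is a per-day Bernoulli thinning with a sampling boost
around events (ward practice: sick patients get measured more), which is
what exercises the indeterminate/excluded labeling branches.  Class
assignment follows a logistic link on age and exposures with centred
covariates, so the marginal event fractions match the configured mix.

Defaults emulate the cohort shape of the multicenter ward study this
package models: median stay 10 days, ~8% AKI, ~15% of AKI progressing to
AKD, onset-day median 7.

Patient ``i`` draws from ``default_rng([seed, i])``: adding patients never
perturbs earlier ones, and a fixed seed reproduces output byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EXPOSURE_FLAGS, Cohort, PatientAdmission, write_cohort

CLASSES = ("no_event", "transient_low", "transient_dip",
           "aki_recover", "aki_akd", "day1_aki")


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 1000
    seed: int = 0

    # admission length: log-normal, clipped
    los_median_days: float = 10.0
    los_sigma: float = 0.8
    los_min: int = 3
    los_max: int = 60

    # event mix (fractions sum to 1 with no-event patients as remainder)
    frac_aki: float = 0.08
    akd_share: float = 0.15            # share of AKI progressing to AKD
    frac_transient: float = 0.08
    transient_dip_share: float = 0.25  # share of transients that are dip-type
    n_day1_aki: int = 0                # planted admission-day onsets

    # SCr trajectory
    baseline_mean: dict = field(default_factory=lambda: {"male": 0.95, "female": 0.78})
    baseline_sd: dict = field(default_factory=lambda: {"male": 0.12, "female": 0.10})
    jitter_sd: float = 0.05
    onset_median_day: float = 7.0
    onset_sigma: float = 0.7
    onset_min_day: int = 2
    aki_fold_mu: float = math.log(2.0)   # log fold-rise at onset
    aki_fold_sigma: float = 0.25
    # antecedent physiology before onset (what makes early prediction
    # possible at all): mild SCr creep (mg/dL, below every threshold) and
    # vital-sign shifts over days onset-2 .. onset+2
    prodrome_scr_creep: float = 0.08
    prodrome_vital_shift: dict = field(default_factory=lambda: {
        "heart_rate": 10.0, "body_temp": 0.45, "resp_rate": 2.5})

    # measurement sparsity
    sampling_prob: float = 0.8
    event_sampling_prob: float = 1.0     # around onset (onset-1 .. onset+7)
    lab_prob: float = 0.7                # non-SCr labs, given a sampled day

    # demographics / schedule
    age_mean: float = 62.0
    age_sd: float = 14.0
    start_date: str = "2016-01-01"
    span_years: int = 5

    # per-admission exposure probabilities and logistic class-link effects
    exposure_prob: dict = field(default_factory=lambda: {
        "nsaid": 0.20, "nephrotoxic_antibiotic": 0.15, "chemotherapy": 0.05,
        "vascular_imaging": 0.08, "surgery": 0.25, "contrast_ct": 0.15,
        "icu_transfer": 0.04,
    })
    covariate_coefs: dict = field(default_factory=lambda: {
        "age_per_decade": 0.15, "surgery": 0.4, "nsaid": 0.3,
        "nephrotoxic_antibiotic": 0.5,
    })

    def validate(self) -> None:
        fracs = (self.frac_transient, self.frac_aki)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("event fractions must be >= 0 and sum to <= 1")
        if not 0 <= self.akd_share <= 1:
            raise ValueError("akd_share must be in [0, 1]")
        if self.akd_share > 0 and self.frac_aki == 0:
            raise ValueError("an AKD fraction requires a nonzero AKI fraction")
        if self.jitter_sd < 0 or self.los_sigma < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class _Patient:
    pid: str
    admission: PatientAdmission
    true_class: str
    baseline: float
    onset_day: float  # nan when eventless
    recovery_day: float
    scr: list  # (day, hour, value)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_class(rng, cfg: SimConfig, age: float, exposures: dict) -> str:
    """Logistic class link with centred covariates (marginal ~ frac_aki)."""
    if cfg.frac_aki <= 0:
        p_aki = 0.0
    else:
        logit = math.log(cfg.frac_aki / (1 - cfg.frac_aki))
        c = cfg.covariate_coefs
        logit += c.get("age_per_decade", 0.0) * (age - cfg.age_mean) / 10.0
        for flag, beta in c.items():
            if flag in exposures:
                logit += beta * (float(exposures[flag]) - cfg.exposure_prob[flag])
        p_aki = _sigmoid(logit)
    if rng.random() < p_aki:
        return "aki_akd" if rng.random() < cfg.akd_share else "aki_recover"
    p_trans = cfg.frac_transient / (1 - cfg.frac_aki) if cfg.frac_aki < 1 else 0.0
    if rng.random() < p_trans:
        return ("transient_dip" if rng.random() < cfg.transient_dip_share
                else "transient_low")
    return "no_event"


def _simulate_patient(idx: int, cfg: SimConfig) -> tuple[_Patient, dict, list]:
    rng = np.random.default_rng([cfg.seed, idx])
    pid = f"P{idx:05d}"
    age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 20, 92))
    sex = "female" if rng.random() < 0.5 else "male"
    los = int(np.clip(round(rng.lognormal(math.log(cfg.los_median_days), cfg.los_sigma)),
                      cfg.los_min, cfg.los_max))
    admit_offset = int(rng.integers(0, cfg.span_years * 365))
    admit = pd.Timestamp(cfg.start_date) + pd.Timedelta(days=admit_offset, hours=10)

    exposures_any = {f: rng.random() < cfg.exposure_prob[f] for f in EXPOSURE_FLAGS}
    true_class = _draw_class(rng, cfg, age, exposures_any)
    if idx < cfg.n_day1_aki:
        true_class = "day1_aki"

    b = float(np.clip(rng.normal(cfg.baseline_mean[sex], cfg.baseline_sd[sex]),
                      0.62, 1.15))
    onset_day: float = math.nan
    recovery_day: float = math.nan
    special: dict[int, float] = {}  # day -> exact planted value (low jitter)

    if true_class == "transient_low":
        b = float(rng.uniform(0.36, 0.50))
        onset_like = int(rng.integers(2, max(3, los)))  # spike day
        special[onset_like] = math.nan  # filled after jittered days exist
        spike_day, spike_delta = onset_like, float(rng.uniform(0.20, 0.27))
    elif true_class == "transient_dip":
        b = float(rng.uniform(1.02, 1.15))
        dip_day = int(rng.integers(2, max(3, los)))
        los = max(los, dip_day + 1)
        depth = float(rng.uniform(0.35, 0.40))
        special[dip_day - 1] = b                      # exact pre-dip anchor
        special[dip_day] = b - depth
        special[dip_day + 1] = b - depth + float(rng.uniform(0.33, 0.37))
    elif true_class in ("aki_recover", "aki_akd"):
        onset = int(np.clip(round(rng.lognormal(math.log(cfg.onset_median_day),
                                                cfg.onset_sigma)),
                            cfg.onset_min_day, max(cfg.onset_min_day, los)))
        los = max(los, onset + 8)
        onset_day = onset
        fold = float(rng.lognormal(cfg.aki_fold_mu, cfg.aki_fold_sigma))
        peak = max(b * fold, max(1.5 * b, b + 0.3) + 0.12)
        # antecedent signature: sub-threshold SCr creep in the 2 days
        # before onset (stays well below every detection threshold); only
        # when a plain pre-onset day remains in the baseline window, so
        # the creep cannot inflate the baseline estimate itself
        if cfg.prodrome_scr_creep > 0 and onset >= 4:
            special[onset - 2] = b + 0.5 * cfg.prodrome_scr_creep
            special[onset - 1] = b + cfg.prodrome_scr_creep
        special[onset] = peak
        if true_class == "aki_recover":
            r = int(rng.integers(3, 7))  # planted recovery day 3..6 post onset
            recovery_day = r
            floor = 1.5 * b + 0.10
            for k in range(1, r):
                frac = k / r
                special[onset + k] = max(peak - frac * (peak - floor), floor)
            special[onset + r] = 1.2 * b - 0.05  # unambiguous recovery dip
            # remaining window days sit at baseline (keeps status robust)
            for k in range(r + 1, 9):
                special[onset + k] = b
        else:
            floor = 1.5 * b + 0.10
            for k in range(1, 9):
                special[onset + k] = max(peak - 0.06 * k * (peak - floor), floor)
    elif true_class == "day1_aki":
        onset_day = 1

    # day-level sampling mask
    in_event_window = lambda d: (not math.isnan(onset_day)
                                 and onset_day - 1 <= d <= onset_day + 7)
    sampled = []
    for d in range(1, los + 1):
        p = cfg.event_sampling_prob if (in_event_window(d) or d in special) \
            else cfg.sampling_prob
        if d == 1 or rng.random() < p:
            sampled.append(d)

    # SCr values on sampled days
    scr: list[tuple[int, float, float]] = []  # (day, hour, value)
    values_so_far: list[float] = []
    for d in sampled:
        hour = 7.5 if d > 1 else 11.0  # day-1 draw after 10:00 admission
        if true_class == "transient_low" and d == spike_day:
            prior = [v for (dd, _h, v) in scr if d - 7 <= dd < d] or [b]
            v = min(prior) + spike_delta
        elif d in special and not math.isnan(special[d]):
            v = special[d] + float(rng.normal(0, 0.01))
        else:
            v = b + float(rng.normal(0, cfg.jitter_sd))
        v = max(v, 0.15)
        scr.append((d, hour, v))
        values_so_far.append(v)
    if true_class == "day1_aki":
        v0 = b + float(rng.normal(0, 0.01))
        scr = [(d, h, v) for (d, h, v) in scr if d != 1]
        scr = [(1, 11.0, v0), (1, 15.0, v0 + 0.05), (1, 20.0, v0 + 0.45)] + scr
        # decay back over the next days
        scr = [(d, h, (v if d == 1 else max(b, v0 + 0.45 - 0.2 * (d - 1))
                       + float(rng.normal(0, 0.01)))) for (d, h, v) in scr]

    discharge = admit.normalize() + pd.Timedelta(days=los - 1, hours=18)
    adm = PatientAdmission(pid, age, sex, admit, discharge,
                           height_cm=float(rng.normal(165, 9)),
                           weight_kg=float(rng.normal(66, 12)))

    # exposure day records
    exp_rows = []
    for flag, present in exposures_any.items():
        if present and los >= 1:
            e_day = int(rng.integers(1, los + 1))
            exp_rows.append((pid, e_day, flag))

    return (_Patient(pid, adm, true_class, b, onset_day, recovery_day, scr),
            exposures_any, exp_rows)


_LAB_DISTS = {
    "hemoglobin": (12.5, 1.8), "albumin": (3.8, 0.5), "platelet": (230, 60),
    "WBC": (8.0, 2.5), "sodium": (139, 3.0), "chloride": (103, 3.0),
    "calcium": (9.2, 0.5), "glucose": (115, 30), "pH": (7.40, 0.03),
    "total_co2": (24, 3.0), "urine_sg": (1.015, 0.005), "aPTT": (32, 4.0),
}
_LAB_LOGNORM = {"CRP": (0.7, 1.0), "ALT": (3.1, 0.5), "ALP": (4.4, 0.35),
                "total_bilirubin": (-0.25, 0.4)}
_VITAL_DISTS = {"heart_rate": (78, 10), "sbp": (120, 15), "dbp": (72, 10),
                "body_temp": (36.8, 0.4), "resp_rate": (16, 2.5)}


def simulate_cohort(cfg: SimConfig = SimConfig()) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground truth table.

    Returns (cohort, ground_truth) where ground_truth has one row per
    patient: true_class, true baseline, onset_day and recovery_day (days
    post onset), all NaN where not applicable.
    """
    cfg.validate()
    admissions: dict[str, PatientAdmission] = {}
    meas_rows = []
    exp_recs: dict[tuple[str, int], dict] = {}
    gt_rows = []
    for idx in range(cfg.n_patients):
        patient, _exp_any, exp_rows = _simulate_patient(idx, cfg)
        rng = np.random.default_rng([cfg.seed, idx, 1])  # labs/vitals substream
        adm = patient.admission
        admissions[patient.pid] = adm
        day0 = adm.admit_time.normalize()
        for d, hour, v in patient.scr:
            meas_rows.append((patient.pid, "SCr",
                              day0 + pd.Timedelta(days=d - 1, hours=hour),
                              round(v, 3)))
        los = (adm.discharge_time.normalize() - day0).days + 1
        scr_by_day = {d: v for d, _h, v in patient.scr}
        onset = patient.onset_day
        vital_gain = float(rng.uniform(0.6, 1.4))  # per-patient prodrome size
        for d in range(1, los + 1):
            sick = (not math.isnan(onset)) and onset - 2 <= d <= onset + 2
            for vital, (mu, sd) in _VITAL_DISTS.items():
                shift = (cfg.prodrome_vital_shift.get(vital, 0.0) * vital_gain
                         if sick else 0.0)
                for k in range(int(rng.integers(2, 5))):
                    meas_rows.append(
                        (patient.pid, vital,
                         day0 + pd.Timedelta(days=d - 1, hours=6 + 5 * k),
                         round(float(rng.normal(mu + shift, sd)), 2)))
            if d in scr_by_day and rng.random() < cfg.lab_prob:
                t = day0 + pd.Timedelta(days=d - 1, hours=7.6)
                bun = scr_by_day[d] * float(rng.uniform(12, 20))
                meas_rows.append((patient.pid, "BUN", t, round(bun, 1)))
                for lab, (mu, sd) in _LAB_DISTS.items():
                    meas_rows.append((patient.pid, lab, t,
                                      round(float(rng.normal(mu, sd)), 3)))
                for lab, (mu, sd) in _LAB_LOGNORM.items():
                    meas_rows.append((patient.pid, lab, t,
                                      round(float(rng.lognormal(mu, sd)), 3)))
        for pid, e_day, flag in exp_rows:
            key = (pid, e_day)
            rec = exp_recs.setdefault(
                key, {"patient_id": pid,
                      "day": day0 + pd.Timedelta(days=e_day - 1),
                      **{f: False for f in EXPOSURE_FLAGS}})
            rec[flag] = True
        gt_rows.append({
            "patient_id": patient.pid, "true_class": patient.true_class,
            "baseline": round(patient.baseline, 3),
            "onset_day": patient.onset_day, "recovery_day": patient.recovery_day,
        })
    measurements = pd.DataFrame(meas_rows,
                                columns=["patient_id", "analyte", "time", "value"])
    measurements = measurements.sort_values(
        ["patient_id", "analyte", "time"], kind="stable").reset_index(drop=True)
    exposures = pd.DataFrame(list(exp_recs.values()),
                             columns=["patient_id", "day", *EXPOSURE_FLAGS])
    if len(exposures):
        exposures["day"] = pd.to_datetime(exposures["day"])
    ground_truth = pd.DataFrame(gt_rows)
    return Cohort(admissions, measurements, exposures), ground_truth


def write_simulated(cohort: Cohort, ground_truth: pd.DataFrame,
                    out_dir: str | Path) -> None:
    """Write the cohort CSVs plus ground_truth.csv (deterministic bytes)."""
    write_cohort(cohort, out_dir)
    ground_truth.to_csv(Path(out_dir) / "ground_truth.csv", index=False,
                        float_format="%.3f")


# ---------------------------------------------------------------------------
# Hand-built fixtures covering every labeling branch
# ---------------------------------------------------------------------------

def make_fixture_cohort() -> tuple[Cohort, dict]:
    """A documented mini-cohort where every labeling branch is represented.

    Returns (cohort, expected): ``expected`` maps patient_id to the branch
    the patient exercises.  Includes the canonical worked example — three
    SCr measurements 0.9, 0.6, 0.9 mg/dL within 48 h — which is AKI under
    the standard criteria (0.9 - 0.6 >= 0.3 within 48 h) but not under the
    refined ones (the 0.6 dip is excluded from the baseline).
    """
    t0 = pd.Timestamp("2020-03-01 10:00")

    def adm(pid, age=55, sex="female", los=12):
        return PatientAdmission(pid, age, sex, t0,
                                t0.normalize() + pd.Timedelta(days=los - 1, hours=18))

    def scr(pid, day_hour_value):
        return [(pid, "SCr", t0.normalize() + pd.Timedelta(days=d - 1, hours=h), v)
                for d, h, v in day_hour_value]

    admissions, rows, expected = {}, [], {}

    admissions["WX"] = adm("WX")  # worked example: standard AKI, refined not
    rows += scr("WX", [(1, 11, 0.9), (2, 9, 0.6), (3, 9, 0.9), (5, 9, 0.9)])
    expected["WX"] = "standard_only_pre_onset_decrease"

    admissions["LOWB"] = adm("LOWB")  # low-baseline transient fluctuation
    rows += scr("LOWB", [(1, 11, 0.45), (2, 9, 0.42), (3, 9, 0.68), (5, 9, 0.45)])
    expected["LOWB"] = "standard_only_low_baseline"

    admissions["TRUE_REC"] = adm("TRUE_REC")  # AKI, recovers on day +3
    rows += scr("TRUE_REC", [(1, 11, 0.8), (2, 9, 0.8), (4, 9, 1.4),
                             (5, 9, 1.3), (7, 9, 0.9)])
    expected["TRUE_REC"] = "aki_recovered"

    admissions["TRUE_AKD"] = adm("TRUE_AKD")  # AKI, stays high through day +7
    rows += scr("TRUE_AKD", [(1, 11, 0.8), (2, 9, 0.8), (4, 9, 1.5), (6, 9, 1.45),
                             (9, 9, 1.4), (11, 9, 1.35)])
    expected["TRUE_AKD"] = "aki_akd"

    admissions["INDET"] = adm("INDET", los=6)  # AKI, no post-onset SCr
    rows += scr("INDET", [(1, 11, 0.8), (2, 9, 0.8), (4, 9, 1.4)])
    expected["INDET"] = "aki_indeterminate"

    admissions["DAY1"] = adm("DAY1")  # onset on admission day
    rows += scr("DAY1", [(1, 11, 0.8), (1, 15, 0.85), (1, 20, 1.25), (3, 9, 0.9)])
    expected["DAY1"] = "excluded_day1_aki"

    admissions["YOUNG"] = adm("YOUNG", age=18)  # under-19 exclusion
    rows += scr("YOUNG", [(1, 11, 0.8), (2, 9, 0.8), (3, 9, 0.8)])
    expected["YOUNG"] = "excluded_age"

    admissions["FEWSCR"] = adm("FEWSCR")  # fewer than 3 SCr measurements
    rows += scr("FEWSCR", [(1, 11, 0.8), (5, 9, 0.8)])
    expected["FEWSCR"] = "excluded_scr_count"

    admissions["LOWGFR"] = adm("LOWGFR", age=75, sex="male")  # eGFR <= 60
    rows += scr("LOWGFR", [(1, 11, 2.0), (2, 9, 2.0), (3, 9, 2.1)])
    expected["LOWGFR"] = "excluded_egfr"

    admissions["NONE"] = adm("NONE")  # flat series, no event
    rows += scr("NONE", [(1, 11, 1.0), (3, 9, 1.0), (5, 9, 1.0), (8, 9, 1.0)])
    expected["NONE"] = "no_event"

    measurements = pd.DataFrame(rows, columns=["patient_id", "analyte", "time", "value"])
    measurements = measurements.sort_values(
        ["patient_id", "analyte", "time"], kind="stable").reset_index(drop=True)
    exposures = pd.DataFrame(columns=["patient_id", "day", *EXPOSURE_FLAGS])
    return Cohort(admissions, measurements, exposures), expected
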