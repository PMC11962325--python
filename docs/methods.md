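# Methods

This note documents the operational definitions, conventions and numerical
choices implemented in `wardaki`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phenotyping definitions

### Calendar conventions

All day-level logic uses local-midnight calendar days; day 1 is the
admission date. Timestamps without a timezone are treated as local
wall-clock (single-country EHR assumption). Each admission is an
independent observation unit; readmissions are not linked.

Windows are half-open and never include the measurement under evaluation:
the 7-day baseline window at evaluation time *t* is (*t* − 7 d, *t*), the
48-hour window for the absolute rule is (*t* − 48 h, *t*). All thresholds
are inclusive (≥ 0.3 mg/dL, ≥ 1.5×) with a 10⁻⁹ mg/dL float tolerance,
and running in µmol/L with `LabelParams.scaled(88.4)` reproduces the
mg/dL labels exactly.

### Standard KDIGO (creatinine-only) detector

A measurement fires when it exceeds the minimum of the prior 48 h by
≥ 0.3 mg/dL, or reaches ≥ 1.5× the minimum of the prior 7 days. The first
firing measurement is the onset; one event per admission. Urine-output
criteria and AKI stages 2–3 are out of scope, as is any outpatient
baseline — the comparator uses the raw in-admission 7-day minimum, and the
audit trail records this.

### Refined baseline and detector

Baseline at *t* = the lowest SCr in (*t* − 7 d, *t*), with a dip-exclusion
rule: candidates are tested lowest-first (earlier measurement wins value
ties) and a candidate is excluded when it lies ≥ 0.3 mg/dL below **both**
the median of the other window values (candidate removed, avoiding
self-comparison) and the most recent other window value. The conjunctive
reading and candidate removal are deliberate: "lower than the median and
recent values" reads as a conjunction, and the cascade to the next-lowest
candidate means a replacement baseline always exists. If every candidate
is excluded the window median serves as baseline (reason `all_excluded`,
no baseline timestamp). An empty window yields *no* baseline; the
evaluation is skipped and recorded, never defaulted to zero.

The refined criterion is conjunctive: Δ ≥ 0.3 mg/dL against the filtered
baseline is always required; the 1.5× ratio is additionally required when
the baseline measurement is older than 48 h. This is the only reading
consistent with the canonical dip example (0.9/0.6/0.9 → not AKI) and with
a minimum-increase rule whose purpose is robustness to minor variations.

Two structural properties follow and are tested: refined AKI implies
standard AKI (the filtered baseline is ≥ the raw window minimum, and the
Δ-conjunct only removes events), and all labels are invariant to a global
time shift. Detection is **not** monotone under increases of arbitrary
post-baseline values: raising a neighbor can push the true baseline
≥ 0.3 mg/dL below the median/recent values, flipping it into the
transient-dip exclusion and removing the event. This is inherent to the
exclusion rule — the dip example's declassification depends on it — so the
monotonicity property test covers the standard detector generally and the
refined detector only under increases of the onset measurement itself.

### Ambiguity

A patient's AKI labeling is ambiguous when the standard criteria fire at a
measurement whose refined baseline is unusable (empty window or all
candidates excluded) and no clean refined onset occurs otherwise. Such
patients are dropped from the prediction tasks with an audit reason; the
definition is the weakest one that makes every retained label
evidence-based.

### AKD (recovery) adjudication

The onset-time baseline is frozen (a moving baseline would make recovery
ill-defined). SCr measurements after onset, up to 7 calendar days past the
onset day (configurable), are scanned: the first value **strictly** below
1.5× baseline marks recovery. Without one, the outcome is AKD only when
the window contains at least `min_post_scr` (default 1) measurement
including one in days 5–7 — otherwise a late recovery cannot be excluded
and the outcome is `indeterminate`, a value (excluded from the AKD task),
not an error.

### Day-level labels

Early-AKI task: days onset−3 … onset−1 are positive; the onset day and
everything after are excluded (`onset_day` / `post_onset`); any day whose
next 7 calendar days (index day included) contain no SCr measurement is
excluded (`no_scr_lookahead`) — onset could not have been observed there —
and this exclusion takes precedence over a 0/1 label. Every excluded day
carries exactly one reason. AKD task: one row per AKI patient at the onset
day, 1 = AKD, 0 = recovered, indeterminate excluded.

### Eligibility

Applied sequentially, a patient counting toward the first rule that fires:
missing age/sex (unevaluable), age < 19, fewer than 3 SCr measurements,
CKD-EPI 2021 eGFR ≤ 60 mL/min/1.73 m² at the first SCr of the first
measurement day, and AKI onset on admission day 1 (at least one prior day
of data is needed for prediction). The filter report reconciles counts
exactly and the filter is idempotent.

## Feature engineering

One row per patient-day: vitals as mean/max/min/count over the day; labs
as the most recent value at or before day end (carried forward within the
admission, provenance-tracked); delta features as current value minus the
median of previous observed values; CKD-EPI 2021 eGFR
(142 · min(SCr/κ,1)^α · max(SCr/κ,1)^−1.2 · 0.9938^age · 1.012 if female);
BUN/Cr ratio; trailing-7-day exposure flags (index day included); age,
sex, BMI. Feature lists are config-driven (`FeatureConfig`) with an
optional per-feature physiologic clipping table, since any specific
42-feature selection is cohort-dependent and not reproducible from first
principles.

Missing data: stage 1 is carry-forward; stage 2, assessed on the training
split after carry-forward, imputes features with < 20% residual
missingness by chained equations (scikit-learn's iterative imputer, 10
round-robin linear-regression iterations, seeded — a documented
simplification of full multiple imputation) and converts features at
≥ 20% to training-quantile categories (default thirds) one-hot encoded
with an explicit missing level. Robust scaling is (x − median)/IQR fitted
on the training split; constant features (IQR 0) are flagged and passed
through. Every cell's provenance is one of
observed/carried/imputed/missing-level/missing. No evaluation-split
statistic can influence any transformation: the imputer and scaler refuse
to fit without training rows, and a leakage audit (rewriting evaluation
rows leaves train-side outputs bit-identical) is part of the test suite.

## Synthetic ward cohorts

The generator emulates the cohort shape of a multicenter general-ward
study: log-normal stays (median 10 d, σ = 0.8, clipped to 3–60 d), ~8% AKI
with ~15% of AKI progressing to AKD, onset-day median 7 (log-normal,
σ = 0.7, earliest day 2 by default), sex-specific baseline SCr
(male 0.95 ± 0.12, female 0.78 ± 0.10 mg/dL), measurement jitter SD
0.05 mg/dL, per-day SCr sampling probability 0.8 rising to 1.0 around
events (ward practice: sick patients are measured more), and an 8%
transient-fluctuation class split between low-baseline bumps
(baseline < 0.6 mg/dL, one-day rise crossing 1.5× the window minimum while
staying < 0.3 mg/dL above it) and normal-baseline one-day dips of
0.35–0.40 mg/dL followed by return — both engineered to fool the standard
criteria but not the refined ones. Class assignment follows a logistic
link on age and exposures with centred covariates, so marginal fractions
match the configured mix. AKI trajectories step to
max(1.5× baseline, baseline + 0.3) + margin at onset and either decay
below 1.5× baseline at a planted recovery day (3–6) or plateau above it
through day 8. A mild antecedent signature precedes onset — a
sub-threshold SCr creep (default 0.08 mg/dL, well below every detection
threshold, and applied only when a plain pre-onset day remains in the
baseline window so the creep cannot inflate the baseline estimate) and
vital-sign shifts (heart rate +10/min, temperature +0.45 °C, respiratory
rate +2.5/min, scaled per patient) over days onset−2 to onset+2 —
emulating the physiology that makes early prediction possible at all. Optional day-1 onsets are planted as several same-day measurements,
the only way an admission-day onset is observable under the refined rule.

Patient *i* draws from `default_rng([seed, i])`, so adding patients never
perturbs earlier ones and output is byte-identical under a fixed seed.

What the generator does **not** emulate: pharmacokinetics, correlated
multi-organ physiology, informative missingness beyond the event-window
sampling boost, drifting baselines, or inter-hospital shift. Passing
planted-event tests therefore demonstrates correctness of the labeling
logic under controlled conditions, not clinical performance on real
wards — the generator's signal structure, not the models, bounds the
reported synthetic AUROCs. One deliberate imperfection is worth noting:
a week-old planted dip can re-enter the baseline when a later ordinary day
jitters ~2σ low (the exclusion rule's recent-value gap then falls below
0.3 mg/dL), so a small fraction (≲ 10%) of dip-type transient patients are
labeled AKI by the refined detector. This is a property of the refined
rule itself, and is why the planted-event specificity check budgets 1%
rather than demanding perfection.

## Prediction harness

Models sit behind one adapter: logistic regression, random forest and
scikit-learn's HistGradientBoosting are built in; xgboost and lightgbm
load lazily as extras. Cross-validation is 5-fold and patient-grouped
(all rows of a patient share a fold — enforced by assertion); a training
fold with a single class raises an error naming the fold. The metric panel
at probability cutoff 0.5 reports accuracy, precision, recall,
specificity (included because the methods text of the source study lists
it, though its tables omit it) and F1, plus AUROC and AUPRC; undefined
ratios are NaN with an explanatory flag rather than exceptions.
Calibration uses 5 equal-count bins and reports the least-squares slope of
observed event rate on mean predicted probability; a degenerate score
distribution is flagged instead of fitted.

The rolling framework simulation groups a labeled cohort by period
(admission year), scores every labelable day, and counts an event as
predicted early when ≥ 1 of its positive-labeled days is flagged at the
cutoff; periods without events report counts with an undefined rate flag.

## Problem sizes

The test suite and acceptance script use 10,000 random trajectories for
the subset/oracle checks, a 1000-patient daily-sampled cohort for
planted-event recovery, a 2000-patient sparse cohort for the
criteria-comparison accounting, and an 800-patient cohort (70/30 patient
split) for the modeling pass — sizes chosen so the full battery completes
in minutes on one CPU while keeping Monte-Carlo noise well inside the
asserted tolerances.
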