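"""Model training, evaluation and the rolling framework simulation.

The harness is deliberately model-agnostic: logistic regression, random
forest and gradient-boosting families sit behind one adapter
(``make_model``).  sklearn's HistGradientBoosting is the shipped default;
xgboost and lightgbm are optional extras loaded lazily.

Evaluation reports the full panel at probability cutoff 0.5 — accuracy,
precision, recall, specificity, F1 — plus AUROC, AUPRC and a binned
calibration summary (5 equal-count bins; the calibration slope is the
least-squares slope of observed event rate on mean predicted probability).

Cross-validation is patient-grouped: all rows of a patient share a fold,
so no patient leaks between training and validation splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GroupKFold

MODEL_FAMILIES = ("logistic", "random_forest", "hist_gbm", "xgboost", "lightgbm")


def make_model(family: str, seed: int = 0, **hyperparams):
    """Instantiate a classifier by family name (uniform adapter)."""
    if family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **hyperparams)
    if family == "random_forest":
        hyperparams.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, **hyperparams)
    if family == "hist_gbm":
        return HistGradientBoostingClassifier(random_state=seed, **hyperparams)
    if family == "xgboost":
        from xgboost import XGBClassifier

        hyperparams.setdefault("n_estimators", 200)
        return XGBClassifier(random_state=seed, eval_metric="logloss", **hyperparams)
    if family == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, **hyperparams)
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


@dataclass
class EvalReport:
    """Metric panel (cutoff 0.5) with optional CV folds and calibration."""

    metrics: dict
    n: int
    folds: list[dict] = field(default_factory=list)
    fold_mean: dict = field(default_factory=dict)
    fold_sd: dict = field(default_factory=dict)
    calibration: dict | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n, "metrics": self.metrics, "folds": self.folds,
            "fold_mean": self.fold_mean, "fold_sd": self.fold_sd,
            "calibration": self.calibration,
        }


def classification_panel(y_true, y_score, cutoff: float = 0.5) -> dict:
    """Confusion-matrix panel at ``cutoff`` plus ranking metrics.

    Undefined ratios (e.g. precision with zero predicted positives, AUPRC
    with zero true positives) are reported as NaN with an explanatory flag
    rather than raised, so callers can aggregate across folds.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_score, dtype=float)
    pred = (p >= cutoff).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    out = {
        "n": n, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / n if n else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }
    pr, rc = out["precision"], out["recall"]
    out["f1"] = (2 * pr * rc / (pr + rc)
                 if pr == pr and rc == rc and (pr + rc) > 0 else np.nan)
    if 0 < y.sum() < n:
        out["auroc"] = float(roc_auc_score(y, p))
        out["auprc"] = float(average_precision_score(y, p))
        out["flags"] = []
    else:
        out["auroc"] = out["auprc"] = np.nan
        out["flags"] = ["single_class:ranking_metrics_undefined"]
    return out


def calibration_summary(y_true, y_score, n_bins: int = 5) -> dict:
    """Equal-count binned calibration and its least-squares slope.

    A degenerate score distribution (all bins share one mean prediction)
    yields slope None with a ``degenerate`` flag.
    """
    y = np.asarray(y_true, dtype=int)
    p = np.asarray(y_score, dtype=float)
    order = np.argsort(p, kind="stable")
    bins = np.array_split(order, n_bins)
    mean_pred = np.array([p[b].mean() for b in bins if len(b)])
    obs_rate = np.array([y[b].mean() for b in bins if len(b)])
    table = [{"bin": i, "n": int(len(b)), "mean_pred": float(mp), "obs_rate": float(orr)}
             for i, (b, mp, orr) in enumerate(zip(bins, mean_pred, obs_rate))]
    if np.ptp(mean_pred) < 1e-12:
        return {"slope": None, "intercept": None, "bins": table,
                "degenerate": True}
    slope, intercept = np.polyfit(mean_pred, obs_rate, 1)
    return {"slope": float(slope), "intercept": float(intercept), "bins": table,
            "degenerate": False}


def train_models(
    X: pd.DataFrame,
    y,
    groups,
    family: str = "hist_gbm",
    n_folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
    cutoff: float = 0.5,
):
    """Patient-grouped cross-validation, then a fit on all rows.

    Returns (model fitted on the full table, EvalReport with per-fold
    metrics and their means/SDs).  Raises ValueError when a training fold
    contains a single class, naming the fold.
    """
    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    hp = hyperparams or {}
    folds = []
    splitter = GroupKFold(n_splits=n_folds)
    for k, (tr, va) in enumerate(splitter.split(X, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training split of fold {k} contains a single class")
        assert not set(groups[tr]) & set(groups[va]), "patient split across folds"
        model = make_model(family, seed=seed, **hp)
        model.fit(X.iloc[tr], y[tr])
        p = model.predict_proba(X.iloc[va])[:, 1]
        folds.append(classification_panel(y[va], p, cutoff))
    keys = ("accuracy", "precision", "recall", "specificity", "f1", "auroc", "auprc")
    with warnings.catch_warnings():
        # folds where a metric is undefined (all-NaN) are skipped silently
        warnings.simplefilter("ignore", RuntimeWarning)
        fold_mean = {k: float(np.nanmean([f[k] for f in folds])) for k in keys}
        fold_sd = {k: float(np.nanstd([f[k] for f in folds], ddof=1)) for k in keys}
    final = make_model(family, seed=seed, **hp)
    final.fit(X, y)
    report = EvalReport(metrics=fold_mean, n=len(y), folds=folds,
                        fold_mean=fold_mean, fold_sd=fold_sd)
    return final, report


def evaluate(model, X: pd.DataFrame, y, cutoff: float = 0.5,
             n_bins: int = 5) -> EvalReport:
    """Full metric panel plus calibration on a held-out table."""
    y = np.asarray(y, dtype=int)
    p = model.predict_proba(X)[:, 1]
    panel = classification_panel(y, p, cutoff)
    cal = calibration_summary(y, p, n_bins)
    return EvalReport(metrics=panel, n=len(y), calibration=cal)


def run_framework_sim(
    day_table: pd.DataFrame,
    X: pd.DataFrame,
    model,
    periods: dict[str, int],
    events: dict[str, int],
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Rolling per-period simulation of the deployed early-warning model.

    ``day_table`` (patient_id, day, label, reason) aligns row-for-row with
    the feature table ``X``; ``periods`` maps each patient to a period
    (e.g. admission year) and ``events`` maps event patients to their onset
    day.  An event counts as predicted early when at least one of its
    positive-labeled days (the 1-3 days before onset; the onset day itself
    for the AKD task) is flagged at ``cutoff``.

    Per period the result row reports patients, events, events predicted
    early (with the rate NaN-flagged when the period has no events), the
    F1 over labelable days, and the alarm count.
    """
    if len(day_table) != len(X):
        raise ValueError("day_table and X must align row-for-row")
    p = model.predict_proba(X)[:, 1]
    t = day_table.reset_index(drop=True).copy()
    t["flag"] = p >= cutoff
    t["period"] = t["patient_id"].map(periods)
    rows = []
    for period, sub in t.groupby("period", sort=True):
        pids = sub["patient_id"].unique()
        ev_pids = [pid for pid in pids if pid in events]
        early = 0
        for pid in ev_pids:
            pos = sub[(sub["patient_id"] == pid) & (sub["label"] == 1)]
            if pos["flag"].any():
                early += 1
        labeled = sub[sub["label"].isin([0, 1])]
        panel = classification_panel(labeled["label"],
                                     t.loc[labeled.index, "flag"].astype(float))
        rows.append({
            "period": period,
            "n_patients": len(pids),
            "n_events": len(ev_pids),
            "n_predicted_early": early,
            "pct_predicted_early": (100.0 * early / len(ev_pids)
                                    if ev_pids else np.nan),
            "f1": panel["f1"],
            "n_alarms": int(labeled["flag"].sum()),
        })
    return pd.DataFrame(rows)
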