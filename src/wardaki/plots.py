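"""ROC / precision-recall / calibration figures for evaluation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve


def plot_roc(y_true, y_score, path: str | Path) -> None:
    fpr, tpr, _ = roc_curve(y_true, y_score)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pr(y_true, y_score, path: str | Path) -> None:
    prec, rec, _ = precision_recall_curve(y_true, y_score)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(rec, prec)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_calibration(calibration: dict, path: str | Path) -> None:
    """Binned calibration plot from a `calibration_summary` dict."""
    mp = np.array([b["mean_pred"] for b in calibration["bins"]])
    orr = np.array([b["obs_rate"] for b in calibration["bins"]])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(mp, orr, "o-")
    lim = max(0.01, mp.max(), orr.max())
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=0.8)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed event rate")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
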