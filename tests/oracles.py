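"""Independent brute-force reference implementations for the labeling rules.

Pure-Python, all-pairs enumerations using the statistics module — kept
deliberately free of the package's windowing/vectorization code so they can
serve as an oracle for it.
"""

from __future__ import annotations

import statistics

HOUR = 3600.0


def brute_baseline(times_h, values, eval_h, window_days=7.0, delta=0.3, tol=1e-9):
    """(baseline value, baseline time or None, reason) by explicit enumeration.

    times_h are plain floats (hours).  Returns None for an empty window.
    """
    window = [(t, v) for t, v in zip(times_h, values)
              if eval_h - window_days * 24 < t < eval_h]
    if not window:
        return None
    for t_c, v_c in sorted(window, key=lambda p: (p[1], p[0])):
        others = list(window)
        others.remove((t_c, v_c))
        if not others:
            return v_c, t_c, "min_window"
        med = statistics.median(v for _t, v in others)
        recent = max(others)[1]  # value of the latest other measurement
        if med - v_c >= delta - tol and recent - v_c >= delta - tol:
            continue
        return v_c, t_c, "min_window"
    return statistics.median(v for _t, v in window), None, "all_excluded"


def brute_standard_onset(times_h, values, min_inc=0.3, ratio=1.5, tol=1e-9):
    """Index of the first standard-KDIGO firing measurement, or None."""
    for i, (t, v) in enumerate(zip(times_h, values)):
        prior48 = [v2 for t2, v2 in zip(times_h, values) if t - 48 < t2 < t]
        prior7d = [v2 for t2, v2 in zip(times_h, values) if t - 168 < t2 < t]
        if prior48 and v - min(prior48) >= min_inc - tol:
            return i
        if prior7d and v >= ratio * min(prior7d) - tol:
            return i
    return None


def brute_refined_onset(times_h, values, min_inc=0.3, ratio=1.5, tol=1e-9):
    """(index, baseline value) of the first refined firing, or (None, None)."""
    for i, (t, v) in enumerate(zip(times_h, values)):
        est = brute_baseline(times_h, values, t, delta=min_inc, tol=tol)
        if est is None:
            continue
        b, b_time, _reason = est
        within48 = b_time is not None and t - b_time <= 48.0
        if v - b >= min_inc - tol and (within48 or v >= ratio * b - tol):
            return i, b
    return None, None


def brute_confusion_panel(y_true, y_pred):
    """Confusion-matrix metric panel by direct counting."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    n = len(y_true)
    out = {"accuracy": (tp + tn) / n}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    if out["precision"] and out["recall"]:
        out["f1"] = 2 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
    else:
        out["f1"] = None
    return out


def ckd_epi_2021_reference(scr, age, sex):
    """Straight transcription of the published 2021 CKD-EPI equation."""
    import math

    kappa = 0.7 if sex == "female" else 0.9
    alpha = -0.241 if sex == "female" else -0.302
    r = scr / kappa
    val = 142.0 * (min(r, 1.0) ** alpha) * (max(r, 1.0) ** -1.2) * (0.9938 ** age)
    if sex == "female":
        val *= 1.012
    return val
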