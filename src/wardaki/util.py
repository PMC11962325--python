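"""Small shared helpers: day indexing, percentage formatting, errors."""

from __future__ import annotations

import pandas as pd

#: mg/dL -> µmol/L conversion factor for creatinine
SCR_UMOL_PER_MGDL = 88.4


class SchemaError(ValueError):
    """A cohort file is structurally unusable (missing columns, bad header)."""


class PipelineError(RuntimeError):
    """Pipeline stages were run out of order or with inconsistent inputs."""


def day_index(ts: pd.Timestamp, admit_time: pd.Timestamp) -> int:
    """Admission-day index of a timestamp; the admission date is day 1.

    Calendar days are bounded by local midnight, so a measurement at 00:30
    the morning after admission falls on day 2 even if fewer than 24 h
    elapsed.
    """
    return (pd.Timestamp(ts).normalize() - pd.Timestamp(admit_time).normalize()).days + 1


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to ``digits`` decimals, as printed in reports.

    Raises ZeroDivisionError for a zero denominator; callers that can see
    empty groups must guard and report an undefined-rate flag instead.
    """
    return round(100.0 * numerator / denominator, digits)
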