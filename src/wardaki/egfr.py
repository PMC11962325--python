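"""Estimated glomerular filtration rate (CKD-EPI 2021, race-free).

The 2021 CKD-EPI creatinine equation estimates GFR (mL/min/1.73 m^2) from
serum creatinine, age and sex:

    eGFR = 142 * min(SCr/k, 1)^a * max(SCr/k, 1)^-1.200
               * 0.9938^age * (1.012 if female else 1)

with k = 0.7 (female) / 0.9 (male) and a = -0.241 (female) / -0.302 (male).
"""

from __future__ import annotations

import numpy as np

_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.241, "male": -0.302}
_SEX_FACTOR = {"female": 1.012, "male": 1.0}


def compute_egfr(scr_mgdl, age_years, sex: str):
    """CKD-EPI 2021 eGFR in mL/min/1.73 m^2.

    Parameters
    ----------
    scr_mgdl : float or array-like
        Serum creatinine in mg/dL; must be > 0.
    age_years : float or array-like
        Age in years; the equation is defined for adults (>= 18).
    sex : {"female", "male"}

    Returns
    -------
    float or ndarray
    """
    if sex not in _KAPPA:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    scr = np.asarray(scr_mgdl, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    ratio = scr / _KAPPA[sex]
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** _ALPHA[sex]
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938 ** np.asarray(age_years, dtype=float)
        * _SEX_FACTOR[sex]
    )
    return float(egfr) if egfr.ndim == 0 else egfr
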