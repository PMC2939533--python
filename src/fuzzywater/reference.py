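"""Reference demographic table of the motivating clinical cohort.

Seventeen autopsy-confirmed Alzheimer patients (sex, age, Mini-Mental
State Examination score, Braak neurofibrillary stage) — the printed
per-subject data used in worked examples and arithmetic checks.  The ten
ALS controls were reported only in aggregate (MMSE 30 throughout) and are
summarized by :func:`control_summary`.
"""

from __future__ import annotations

import pandas as pd

_AD_ROWS = [
    (1, "M", 78, 23, "VI"),
    (2, "F", 78, 17, "VI"),
    (3, "F", 57, 25, "V"),
    (4, "F", 79, 20, "VI"),
    (5, "M", 74, 19, "VI"),
    (6, "M", 76, 20, "VI"),
    (7, "F", 83, 10, "VI"),
    (8, "F", 83, 20, "VI"),
    (9, "M", 68, 20, "VI"),
    (10, "M", 84, 18, "VI"),
    (11, "M", 83, 16, "V"),
    (12, "M", 80, 18, "VI"),
    (13, "M", 81, 20, "VI"),
    (14, "M", 80, 21, "V"),
    (15, "F", 86, 16, "VI"),
    (16, "F", 80, 15, "V"),
    (17, "F", 87, 20, "V"),
]


def ad_demographics() -> pd.DataFrame:
    """Per-patient demographics of the AD group."""
    return pd.DataFrame(
        _AD_ROWS, columns=["patient", "sex", "age", "mmse", "braak_stage"]
    ).set_index("patient")


def ad_summary() -> pd.DataFrame:
    """Mean, sample SD, min and max of age and MMSE in the AD group."""
    df = ad_demographics()
    rows = {}
    for col in ("age", "mmse"):
        x = df[col]
        rows[col] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": int(x.min()),
            "max": int(x.max()),
        }
    return pd.DataFrame(rows).T


def control_summary() -> dict:
    """Aggregate description of the control group (per-subject data unpublished)."""
    return {"n": 10, "sex_f_m": (3, 7), "age_mean": 55.9, "age_sd": 7.6,
            "mmse_mean": 30.0, "mmse_sd": 0.0}
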