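"""Reference ("baseline") creatinine estimators.

A serum-creatinine rise can only be staged against a reference value. The
choice of reference is a study decision, so several estimators are offered:

* a statistic (min / mean / first) of a fixed window at the start of the
  series, broadcast to every hour;
* the same statistic over a rolling trailing window that *excludes* the
  current hour, so a rising creatinine is compared to its past, not itself;
* a constant (e.g. a known pre-operative creatinine);
* an expected creatinine derived by inverting the Cockcroft–Gault
  creatinine-clearance formula under an assumed GFR (75 ml/min by default),
  using the adjusted body weight when a height is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATISTICS = ("min", "mean", "first")
MODES = ("fixed_start", "rolling")

_CM_PER_INCH = 2.54


def window_baseline(
    scr: np.ndarray, statistic: str, mode: str, window_hours: int
) -> np.ndarray:
    """Windowed baseline over an hourly creatinine series (NaN = missing).

    ``fixed_start``: the statistic of the non-missing values in hours
    ``[0, window_hours)`` is broadcast to every hour. ``rolling``: at hour
    ``t`` the statistic is taken over the non-missing values in
    ``[t - window_hours, t)`` — trailing and excluding hour ``t`` itself.
    Hours whose window holds no observation get a missing baseline.
    """
    if window_hours < 1:
        raise ValueError("window_hours must be >= 1")
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")

    scr = np.asarray(scr, dtype=float)
    n = scr.size
    if mode == "fixed_start":
        head = scr[: min(window_hours, n)]
        head = head[~np.isnan(head)]
        if head.size == 0:
            return np.full(n, np.nan)
        if statistic == "min":
            value = head.min()
        elif statistic == "mean":
            value = head.mean()
        else:
            value = head[0]
        return np.full(n, float(value))

    shifted = pd.Series(scr).shift(1)
    roll = shifted.rolling(window_hours, min_periods=1)
    if statistic == "min":
        out = roll.min()
    elif statistic == "mean":
        out = roll.mean()
    else:
        out = roll.apply(_first_valid, raw=True)
    return out.to_numpy()


def _first_valid(window: np.ndarray) -> float:
    valid = window[~np.isnan(window)]
    return valid[0] if valid.size else np.nan


def constant_baseline(value: float, length: int) -> np.ndarray:
    """A fixed reference creatinine (mg/dl) at every hour."""
    if value <= 0:
        raise ValueError("baseline creatinine must be > 0")
    return np.full(length, float(value))


def cockcroft_gault_clearance(age: float, weight: float, sex: str, scr: float) -> float:
    """Cockcroft–Gault creatinine clearance, ml/min.

    (140 − age) × weight [kg] × (0.85 if female) / (72 × SCr [mg/dl]).
    """
    _check_cg_inputs(age, weight, sex)
    if scr <= 0:
        raise ValueError("creatinine must be > 0")
    return (140.0 - age) * weight * _sex_factor(sex) / (72.0 * scr)


def expected_scr_from_gfr(
    age: float,
    weight: float,
    sex: str,
    assumed_gfr: float = 75.0,
    height: float | None = None,
) -> float:
    """Expected creatinine (mg/dl) under an assumed GFR — Cockcroft–Gault inverted.

    If ``height`` (cm) is given, ``weight`` is replaced by the adjusted body
    weight before evaluation.
    """
    if assumed_gfr <= 0:
        raise ValueError("assumed GFR must be > 0")
    _check_cg_inputs(age, weight, sex)
    effective_weight = (
        adjusted_body_weight(height, weight, sex) if height is not None else weight
    )
    return (140.0 - age) * effective_weight * _sex_factor(sex) / (72.0 * assumed_gfr)


def adjusted_body_weight(height: float, actual_weight: float, sex: str) -> float:
    """Adjusted body weight: IBW + 0.4 × (actual − IBW).

    Ideal body weight (IBW) by the Devine estimate — 50 kg (male) or
    45.5 kg (female) plus 2.3 kg per inch of height over five feet.
    Patients lighter than their IBW keep their actual weight.
    """
    if height <= 0 or actual_weight <= 0:
        raise ValueError("height and weight must be > 0")
    inches_over = max(height / _CM_PER_INCH - 60.0, 0.0)
    ibw = (50.0 if _sex_factor(sex) == 1.0 else 45.5) + 2.3 * inches_over
    if actual_weight < ibw:
        return actual_weight
    return ibw + 0.4 * (actual_weight - ibw)


def _sex_factor(sex: str) -> float:
    if sex == "female":
        return 0.85
    if sex == "male":
        return 1.0
    raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")


def _check_cg_inputs(age: float, weight: float, sex: str) -> None:
    _sex_factor(sex)
    if age >= 140:
        raise ValueError("age >= 140 makes the Cockcroft-Gault formula non-positive")
    if age <= 0:
        raise ValueError("age must be > 0")
    if weight <= 0:
        raise ValueError("weight must be > 0")
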