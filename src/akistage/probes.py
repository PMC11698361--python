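"""The four independent KDIGO staging probes, evaluated at every hour.

Each probe maps hourly input series to an hourly stage series with values
0–3 or NaN (undefined — the evidence for that hour is missing):

* urine output: mean per-kg rate over trailing windows ending at the
  current hour — < 0.5 ml/kg/h sustained ≥ 6 h is stage 1, ≥ 12 h stage 2;
  < 0.3 ml/kg/h sustained ≥ 24 h, or anuria ≥ 12 h, stage 3. Missing hours
  break windows: evaluation restarts after a gap.
* relative creatinine: ratio to baseline — 1.5–1.9× stage 1, 2–2.9×
  stage 2, ≥ 3× stage 3.
* absolute creatinine: ≥ 0.3 mg/dl over the (48-h rolling, by default)
  baseline is stage 1; ≥ 4 mg/dl is stage 3 irrespective of any baseline.
* dialysis: active renal replacement therapy is stage 3.

All threshold comparisons carry a small epsilon guard: a value within
epsilon of a threshold is treated as exactly at the threshold, so that
floating-point noise from upstream arithmetic (e.g. back-distributed urine
shares) cannot flip a stage.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Trailing-window duration thresholds, hours.
STAGE1_UO_HOURS = 6
STAGE2_UO_HOURS = 12
STAGE3_UO_HOURS = 24
ANURIA_HOURS = 12

#: Per-kg urine-flow thresholds, ml/kg/h.
UO_RATE_STAGE12 = 0.5
UO_RATE_STAGE3 = 0.3

#: Relative creatinine fold-change band edges.
REL_STAGE1 = 1.5
REL_STAGE2 = 2.0
REL_STAGE3 = 3.0

#: Absolute creatinine thresholds, mg/dl.
ABS_DELTA_STAGE1 = 0.3
ABS_LEVEL_STAGE3 = 4.0


@dataclasses.dataclass(frozen=True)
class ProbeConfig:
    """Tunables shared by the probes.

    ``anuria_threshold`` (ml/kg/h): mean flow at or below this counts as
    anuria; 0.0 is strict anuria. ``epsilon``: comparison tolerance.
    """

    anuria_threshold: float = 0.0
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.anuria_threshold < UO_RATE_STAGE3:
            raise ValueError("anuria threshold must be in [0, 0.3) ml/kg/h")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


# Epsilon-guarded comparisons: |x - t| <= eps counts as exactly at t.
def _below(x, threshold, eps):
    return x < threshold - eps


def _at_least(x, threshold, eps):
    return x >= threshold - eps


def _at_most(x, threshold, eps):
    return x <= threshold + eps


def uo_stage_series(
    uo_ml: np.ndarray, weight: float, cfg: ProbeConfig = ProbeConfig()
) -> np.ndarray:
    """Urine-output stage at every hour of a contiguous hourly series.

    At hour ``t``, every trailing window of defined hours ending at ``t``
    (not crossing a missing hour) is examined via its mean per-kg rate; the
    highest stage whose rate/duration criterion some window satisfies wins.
    Hours with missing urine output are undefined (NaN).
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    uo_ml = np.asarray(uo_ml, dtype=float)
    n = uo_ml.size
    eps = cfg.epsilon
    rate = uo_ml / weight
    stage = np.where(np.isnan(rate), np.nan, 0.0)

    defined = ~np.isnan(rate)
    # contiguous runs of defined hours
    run_start = 0
    for t in range(n):
        if not defined[t]:
            run_start = t + 1
            continue
        length = t - run_start + 1
        if length < STAGE1_UO_HOURS:
            continue
        window = rate[run_start : t + 1]
        csum = np.cumsum(window[::-1])  # trailing sums: csum[w-1] over last w hours
        widths = np.arange(1, length + 1)
        means = csum / widths
        s = 0.0
        if np.any(_below(means[STAGE1_UO_HOURS - 1 :], UO_RATE_STAGE12, eps)):
            s = 1.0
        if length >= STAGE2_UO_HOURS and np.any(
            _below(means[STAGE2_UO_HOURS - 1 :], UO_RATE_STAGE12, eps)
        ):
            s = 2.0
        if length >= ANURIA_HOURS and np.any(
            _at_most(means[ANURIA_HOURS - 1 :], cfg.anuria_threshold, eps)
        ):
            s = 3.0
        if length >= STAGE3_UO_HOURS and np.any(
            _below(means[STAGE3_UO_HOURS - 1 :], UO_RATE_STAGE3, eps)
        ):
            s = 3.0
        stage[t] = s
    return stage


def relative_scr_stage_series(
    scr: np.ndarray, baseline: np.ndarray, cfg: ProbeConfig = ProbeConfig()
) -> np.ndarray:
    """Stage from the creatinine fold-change over its baseline, per hour."""
    scr = np.asarray(scr, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if scr.shape != baseline.shape:
        raise ValueError("creatinine and baseline series must align")
    both = ~np.isnan(scr) & ~np.isnan(baseline)
    if np.any(baseline[both] <= 0):
        raise ValueError("baseline creatinine must be > 0 where defined")
    eps = cfg.epsilon

    stage = np.full(scr.shape, np.nan)
    with np.errstate(invalid="ignore"):
        ratio = scr / baseline
    r = ratio[both]
    s = np.zeros(r.shape)
    s[_at_least(r, REL_STAGE1, eps)] = 1.0
    s[_at_least(r, REL_STAGE2, eps)] = 2.0
    s[_at_least(r, REL_STAGE3, eps)] = 3.0
    stage[both] = s
    return stage


def absolute_scr_stage_series(
    scr: np.ndarray, baseline: np.ndarray, cfg: ProbeConfig = ProbeConfig()
) -> np.ndarray:
    """Stage from the absolute creatinine elevation, per hour.

    Creatinine at or above 4 mg/dl is stage 3 regardless of baseline; an
    elevation of at least 0.3 mg/dl over baseline is stage 1. Hours where
    the creatinine is missing — or where it is below 4 mg/dl and no
    baseline is defined — are undefined.
    """
    scr = np.asarray(scr, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if scr.shape != baseline.shape:
        raise ValueError("creatinine and baseline series must align")
    eps = cfg.epsilon

    stage = np.full(scr.shape, np.nan)
    has_scr = ~np.isnan(scr)
    high = has_scr & _at_least(scr, ABS_LEVEL_STAGE3, eps)
    stage[high] = 3.0
    both = has_scr & ~high & ~np.isnan(baseline)
    with np.errstate(invalid="ignore"):
        delta = scr - baseline
    stage[both] = np.where(_at_least(delta[both], ABS_DELTA_STAGE1, eps), 1.0, 0.0)
    return stage


def dialysis_stage_series(dialysis: np.ndarray) -> np.ndarray:
    """Stage 3 wherever renal replacement therapy is active, else 0."""
    dialysis = np.asarray(dialysis, dtype=bool)
    return np.where(dialysis, 3.0, 0.0)
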