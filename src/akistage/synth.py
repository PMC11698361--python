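"""Synthetic patients with programmed AKI trajectories, plus a naive oracle.

A trajectory is a list of piecewise-constant segments (per-kg urine flow,
creatinine, dialysis status). The generator emits raw-format tables the
way an ICU chart produces them — urine-bag volumes aggregated over
irregular read intervals, creatinine drawn sparsely, dialysis recorded at
status changes — together with the exact hourly ground truth, so every
stage of the pipeline can be exercised without any external data.

``oracle_stage`` re-derives the staging from the ground truth by exhaustive
per-hour scans and plain-Python threshold checks. It shares no code with
the probes or baselines modules and exists purely as an independent
reference implementation for equivalence testing. Trajectories are test
vectors, not physiology: real creatinine kinetics are smooth, not
piecewise constant.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import BaselineSpec, PipelineConfig
from .data_model import HourlyFrame

_ANCHOR = pd.Timestamp("2023-01-01 00:00:00")


class Segment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    duration_h: int = Field(ge=1)
    uo_rate_ml_kg_h: float = Field(ge=0)
    scr_mg_dl: float = Field(gt=0)
    dialysis: bool = False


class TrajectorySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    subject_id: str = "synthetic-001"
    segments: list[Segment]
    weight_kg: float = Field(default=70.0, gt=0)
    height_cm: float | None = None
    age_years: float = 60.0
    sex: str = "male"
    #: urine-bag read intervals are drawn uniformly from 1..this many hours
    uo_record_interval_h: int = Field(default=1, ge=1)
    #: creatinine draw spacing within a segment (draws also occur at
    #: segment starts, so piecewise-constant truth is exactly recoverable)
    scr_draw_interval_h: int = Field(default=24, ge=1)
    seed: int = 0

    @property
    def n_hours(self) -> int:
        return sum(s.duration_h for s in self.segments)


@dataclasses.dataclass
class GeneratedPatient:
    spec: TrajectorySpec
    uo: pd.DataFrame
    scr: pd.DataFrame
    dialysis: pd.DataFrame
    demographics: pd.DataFrame
    truth: HourlyFrame


def _truth_arrays(spec: TrajectorySpec):
    uo, scr, rrt = [], [], []
    for seg in spec.segments:
        uo.extend([seg.uo_rate_ml_kg_h * spec.weight_kg] * seg.duration_h)
        scr.extend([seg.scr_mg_dl] * seg.duration_h)
        rrt.extend([seg.dialysis] * seg.duration_h)
    return np.array(uo), np.array(scr), np.array(rrt, dtype=bool)


def generate_patient(spec: TrajectorySpec) -> GeneratedPatient:
    """Emit raw tables plus the exact hourly ground truth, deterministically.

    Urine records aggregate the programmed hourly volumes over read
    intervals of 1..``uo_record_interval_h`` hours (never crossing a
    segment boundary, and the stay's first record covers hour 0 alone), so
    back-distribution must recover the programmed values. Record
    timestamps carry random minute offsets to exercise hour flooring.
    """
    rng = np.random.default_rng(spec.seed)
    uo_truth, scr_truth, rrt_truth = _truth_arrays(spec)
    n = spec.n_hours

    def ts(hour: int) -> pd.Timestamp:
        return _ANCHOR + pd.Timedelta(hours=hour, minutes=int(rng.integers(0, 60)))

    # urine-bag reads
    uo_rows = []
    seg_bounds = np.cumsum([0] + [s.duration_h for s in spec.segments])
    first = True
    for start, stop in zip(seg_bounds[:-1], seg_bounds[1:]):
        h = start
        while h < stop:
            width = 1 if first else int(rng.integers(1, spec.uo_record_interval_h + 1))
            first = False
            end = min(h + width, stop)  # never cross a segment boundary
            uo_rows.append(
                {
                    "subject_id": spec.subject_id,
                    "timestamp": ts(end - 1),
                    "volume_ml": float(uo_truth[h:end].sum()),
                }
            )
            h = end

    # creatinine draws: each segment start, then every draw interval
    scr_rows = []
    for start, stop in zip(seg_bounds[:-1], seg_bounds[1:]):
        for h in range(start, stop, spec.scr_draw_interval_h):
            scr_rows.append(
                {
                    "subject_id": spec.subject_id,
                    "timestamp": ts(h),
                    "scr_mg_dl": float(scr_truth[h]),
                }
            )

    # dialysis status: hour 0, then every change
    rrt_rows = [
        {"subject_id": spec.subject_id, "timestamp": ts(0), "active": bool(rrt_truth[0])}
    ]
    for h in range(1, n):
        if rrt_truth[h] != rrt_truth[h - 1]:
            rrt_rows.append(
                {"subject_id": spec.subject_id, "timestamp": ts(h), "active": bool(rrt_truth[h])}
            )

    demographics = pd.DataFrame(
        [
            {
                "subject_id": spec.subject_id,
                "weight_kg": spec.weight_kg,
                "height_cm": spec.height_cm if spec.height_cm is not None else np.nan,
                "age_years": spec.age_years,
                "sex": spec.sex,
            }
        ]
    )
    truth = HourlyFrame(
        subject_id=spec.subject_id,
        anchor=_ANCHOR,
        uo_ml=uo_truth,
        scr=scr_truth,
        dialysis=rrt_truth,
        weight=spec.weight_kg,
    )
    return GeneratedPatient(
        spec=spec,
        uo=pd.DataFrame(uo_rows),
        scr=pd.DataFrame(scr_rows),
        dialysis=pd.DataFrame(rrt_rows),
        demographics=demographics,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Random trajectory sampling (for equivalence testing and cohort emission)

_UO_RATES = (0.0, 0.05, 0.1, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.6, 0.8, 1.0, 1.5)
_SCR_VALUES = (0.6, 0.8, 1.0, 1.2, 1.4, 1.8, 2.1, 2.6, 3.1, 4.2)


def sample_trajectory(subject_id: str, rng: np.random.Generator, max_hours: int = 72) -> TrajectorySpec:
    """Draw a random piecewise-constant trajectory of at most ``max_hours``.

    Rates and creatinine values are drawn from grids that straddle the
    staging thresholds, so boundary behaviour is exercised often.
    """
    n_segments = int(rng.integers(1, 5))
    remaining = max_hours
    segments = []
    for i in range(n_segments):
        if remaining < 1:
            break
        hi = max(remaining - (n_segments - i - 1), 1)
        duration = int(rng.integers(1, hi + 1))
        remaining -= duration
        segments.append(
            Segment(
                duration_h=duration,
                uo_rate_ml_kg_h=float(rng.choice(_UO_RATES)),
                scr_mg_dl=float(rng.choice(_SCR_VALUES)),
                dialysis=bool(rng.random() < 0.15),
            )
        )
    return TrajectorySpec(
        subject_id=subject_id,
        segments=segments,
        weight_kg=float(rng.choice((50.0, 70.0, 90.0))),
        uo_record_interval_h=int(rng.integers(1, 5)),
        scr_draw_interval_h=int(rng.choice((6, 12, 24))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(n_subjects: int, seed: int, max_hours: int = 72) -> list[GeneratedPatient]:
    rng = np.random.default_rng(seed)
    return [
        generate_patient(sample_trajectory(f"synth-{i:04d}", rng, max_hours))
        for i in range(n_subjects)
    ]


def cohort_tables(patients: list[GeneratedPatient]):
    """Concatenate generated patients into the four standard raw tables."""
    uo = pd.concat([p.uo for p in patients], ignore_index=True)
    scr = pd.concat([p.scr for p in patients], ignore_index=True)
    rrt = pd.concat([p.dialysis for p in patients], ignore_index=True)
    demo = pd.concat([p.demographics for p in patients], ignore_index=True)
    return uo, scr, rrt, demo


# ---------------------------------------------------------------------------
# Independent brute-force staging oracle


def _oracle_baseline(scr: list[float], spec: BaselineSpec, demo: dict) -> list[float]:
    n = len(scr)
    if spec.method == "constant":
        return [spec.constant_value] * n
    if spec.method == "expected_gfr":
        weight = demo["weight_kg"]
        if demo.get("height_cm") is not None and not (
            isinstance(demo.get("height_cm"), float) and math.isnan(demo["height_cm"])
        ):
            over = max(demo["height_cm"] / 2.54 - 60.0, 0.0)
            ibw = (50.0 if demo["sex"] == "male" else 45.5) + 2.3 * over
            if weight >= ibw:
                weight = ibw + 0.4 * (weight - ibw)
        factor = 0.85 if demo["sex"] == "female" else 1.0
        value = (140.0 - demo["age_years"]) * weight * factor / (72.0 * spec.assumed_gfr)
        return [value] * n

    mode, statistic = spec.method.rsplit("_", 1)
    w = spec.window_hours

    def stat(values: list[float]) -> float:
        values = [v for v in values if not math.isnan(v)]
        if not values:
            return math.nan
        if statistic == "min":
            return min(values)
        if statistic == "mean":
            return sum(values) / len(values)
        return values[0]

    if mode == "fixed_window":
        value = stat(scr[:w])
        return [value] * n
    return [stat(scr[max(t - w, 0) : t]) for t in range(n)]


def oracle_stage(
    truth: HourlyFrame,
    config: PipelineConfig = PipelineConfig(),
    demographics: dict | None = None,
) -> pd.DataFrame:
    """Stage a gap-free hourly frame by exhaustive scanning.

    Every admissible trailing window at every hour is examined directly;
    the result has the same schema as the pipeline output. ``demographics``
    (keys ``weight_kg``, ``height_cm``, ``age_years``, ``sex``) is needed
    only for the expected-GFR baseline.
    """
    eps = config.probes.epsilon
    anuria = config.probes.anuria_threshold_ml_kg_h
    n = truth.n_hours
    rate = [u / truth.weight for u in truth.uo_ml]

    uo_stage: list[int | None] = []
    for t in range(n):
        if math.isnan(rate[t]):
            uo_stage.append(None)
            continue
        best = 0
        for w in range(1, t + 2):
            window = rate[t - w + 1 : t + 1]
            if any(math.isnan(x) for x in window):
                break
            mean = sum(window) / w
            if w >= 6 and mean < 0.5 - eps:
                best = max(best, 1)
            if w >= 12 and mean < 0.5 - eps:
                best = max(best, 2)
            if w >= 12 and mean <= anuria + eps:
                best = max(best, 3)
            if w >= 24 and mean < 0.3 - eps:
                best = max(best, 3)
        uo_stage.append(best)

    demo = demographics or {
        "weight_kg": truth.weight,
        "height_cm": None,
        "age_years": 60.0,
        "sex": "male",
    }
    scr = [float(v) for v in truth.scr]
    rel_base = _oracle_baseline(scr, config.baseline.relative, demo)
    abs_base = _oracle_baseline(scr, config.baseline.absolute, demo)

    rel_stage: list[int | None] = []
    abs_stage: list[int | None] = []
    for t in range(n):
        if math.isnan(scr[t]):
            rel_stage.append(None)
            abs_stage.append(None)
            continue
        if math.isnan(rel_base[t]):
            rel_stage.append(None)
        else:
            r = scr[t] / rel_base[t]
            if r >= 3.0 - eps:
                rel_stage.append(3)
            elif r >= 2.0 - eps:
                rel_stage.append(2)
            elif r >= 1.5 - eps:
                rel_stage.append(1)
            else:
                rel_stage.append(0)
        if scr[t] >= 4.0 - eps:
            abs_stage.append(3)
        elif math.isnan(abs_base[t]):
            abs_stage.append(None)
        elif scr[t] - abs_base[t] >= 0.3 - eps:
            abs_stage.append(1)
        else:
            abs_stage.append(0)

    rrt_stage = [3 if active else 0 for active in truth.dialysis]

    overall: list[int | None] = []
    for t in range(n):
        defined = [s for s in (uo_stage[t], abs_stage[t], rel_stage[t], rrt_stage[t]) if s is not None]
        overall.append(max(defined) if defined else None)

    return pd.DataFrame(
        {
            "subject_id": truth.subject_id,
            "hour_index": np.arange(n),
            "timestamp": truth.timestamps,
            "uo_stage": pd.array(uo_stage, dtype="Int64"),
            "abs_scr_stage": pd.array(abs_stage, dtype="Int64"),
            "rel_scr_stage": pd.array(rel_stage, dtype="Int64"),
            "dialysis_stage": pd.array(rrt_stage, dtype="Int64"),
            "overall_stage": pd.array(overall, dtype="Int64"),
        }
    )
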