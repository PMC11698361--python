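"""Per-subject orchestration: raw tables → hourly grid → baselines → probes.

The output is one row per hour of the subject's observation span (first to
last observed hour, no extrapolation) carrying the four component stages
and the overall stage. The overall stage is the maximum over the defined
components at that hour; a component that is undefined never masks a
defined one, and the overall stage is undefined only when every component
is.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import preprocessing, probes
from .config import PipelineConfig, compute_baseline
from .data_model import (
    HourlyFrame,
    RESULT_COLUMNS,
    STAGE_COLUMNS,
    collapse_hourly,
    grid_span,
    hour_indices,
)


class SubjectError(RuntimeError):
    """A subject could not be classified; carries the subject context."""

    def __init__(self, subject_id: str, cause: Exception):
        super().__init__(f"subject {subject_id}: {cause}")
        self.subject_id = subject_id
        self.cause = cause


def _stage_column(values: np.ndarray) -> pd.array:
    out = pd.array(values, dtype="Float64").round(0)
    return out.astype("Int64")


def build_hourly_frame(
    subject_id: str,
    uo: pd.DataFrame,
    scr: pd.DataFrame,
    rrt: pd.DataFrame,
    weight: float,
    config: PipelineConfig,
) -> HourlyFrame:
    """Collapse one subject's raw tables to the hourly grid and up-sample."""
    c_uo = collapse_hourly(uo, "volume_ml", "sum")
    c_scr = collapse_hourly(scr, "scr_mg_dl", "last")
    c_rrt = collapse_hourly(rrt, "active", "any")
    anchor, n = grid_span({"uo": c_uo, "scr": c_scr, "rrt": c_rrt})

    uo_h = hour_indices(c_uo, anchor)
    scr_h = hour_indices(c_scr, anchor)
    rrt_h = hour_indices(c_rrt, anchor)

    if config.preprocessing.enabled:
        policy = config.preprocessing.gap_policy()
        uo_series = preprocessing.distribute_urine_output(
            uo_h, c_uo["volume_ml"].to_numpy(), n, policy
        )
        scr_series = preprocessing.carry_forward_creatinine(
            scr_h, c_scr["scr_mg_dl"].to_numpy(), n, policy
        )
    else:
        uo_series = preprocessing.place_without_imputation(
            uo_h, c_uo["volume_ml"].to_numpy(), n
        )
        scr_series = preprocessing.place_without_imputation(
            scr_h, c_scr["scr_mg_dl"].to_numpy(), n
        )
    rrt_series = preprocessing.expand_dialysis(
        rrt_h, c_rrt["active"].to_numpy() if not c_rrt.empty else np.array([]), n
    )

    return HourlyFrame(
        subject_id=subject_id,
        anchor=anchor,
        uo_ml=uo_series,
        scr=scr_series,
        dialysis=rrt_series,
        weight=weight,
    )


def stage_hourly_frame(
    frame: HourlyFrame,
    config: PipelineConfig = PipelineConfig(),
    demographics: pd.Series | None = None,
) -> pd.DataFrame:
    """Run all four probes on a ready hourly frame and aggregate."""
    probe_cfg = config.probes.probe_config()

    rel_base = compute_baseline(frame.scr, config.baseline.relative, demographics)
    abs_base = compute_baseline(frame.scr, config.baseline.absolute, demographics)

    uo_stage = probes.uo_stage_series(frame.uo_ml, frame.weight, probe_cfg)
    rel_stage = probes.relative_scr_stage_series(frame.scr, rel_base, probe_cfg)
    abs_stage = probes.absolute_scr_stage_series(frame.scr, abs_base, probe_cfg)
    rrt_stage = probes.dialysis_stage_series(frame.dialysis)

    stacked = np.vstack([uo_stage, abs_stage, rel_stage, rrt_stage])
    all_nan = np.isnan(stacked).all(axis=0)
    with np.errstate(all="ignore"):
        overall = np.nanmax(stacked, axis=0)
    overall[all_nan] = np.nan

    return pd.DataFrame(
        {
            "subject_id": frame.subject_id,
            "hour_index": np.arange(frame.n_hours),
            "timestamp": frame.timestamps,
            "uo_stage": _stage_column(uo_stage),
            "abs_scr_stage": _stage_column(abs_stage),
            "rel_scr_stage": _stage_column(rel_stage),
            "dialysis_stage": _stage_column(rrt_stage),
            "overall_stage": _stage_column(overall),
        }
    )


def classify_subject(
    subject_id: str,
    uo: pd.DataFrame,
    scr: pd.DataFrame,
    rrt: pd.DataFrame,
    demographics: pd.Series,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Stage one subject end to end; raw tables hold only this subject's rows."""
    try:
        weight = float(demographics["weight_kg"])
        frame = build_hourly_frame(subject_id, uo, scr, rrt, weight, config)
        return stage_hourly_frame(frame, config, demographics)
    except SubjectError:
        raise
    except Exception as exc:
        raise SubjectError(subject_id, exc) from exc


@dataclasses.dataclass
class CohortResult:
    staging: pd.DataFrame  # concatenated per-hour staging rows
    failures: list[tuple[str, str]]  # (subject_id, reason)


def classify_cohort(
    uo: pd.DataFrame,
    scr: pd.DataFrame,
    rrt: pd.DataFrame,
    demo: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> CohortResult:
    """Stage every subject appearing in any measurement table.

    Per-subject failures are collected, not fatal, unless every subject
    fails. Results are ordered by subject id.
    """
    subjects = sorted(
        set(uo["subject_id"].astype(str))
        | set(scr["subject_id"].astype(str))
        | set(rrt["subject_id"].astype(str))
    )
    demo_idx = demo.set_index(demo["subject_id"].astype(str))

    results: list[pd.DataFrame] = []
    failures: list[tuple[str, str]] = []
    for sid in subjects:
        try:
            if sid not in demo_idx.index:
                raise ValueError("no demographics row")
            row = demo_idx.loc[sid]
            if isinstance(row, pd.DataFrame):
                row = row.iloc[0]
            results.append(
                classify_subject(
                    sid,
                    uo[uo["subject_id"].astype(str) == sid],
                    scr[scr["subject_id"].astype(str) == sid],
                    rrt[rrt["subject_id"].astype(str) == sid],
                    row,
                    config,
                )
            )
        except Exception as exc:
            failures.append((sid, str(exc)))
    if subjects and not results:
        raise RuntimeError(f"all {len(subjects)} subjects failed: {failures}")
    staging = (
        pd.concat(results, ignore_index=True)
        if results
        else pd.DataFrame(columns=list(RESULT_COLUMNS))
    )
    return CohortResult(staging=staging, failures=failures)


@dataclasses.dataclass
class SubjectSummary:
    subject_id: str
    max_overall_stage: int | None
    first_aki_hour: int | None
    first_stage_hour: dict[str, int | None]
    hours_at_stage: dict[int, int]
    n_hours: int
    n_undefined_hours: int
    indeterminate: bool


def summarize_subject(result: pd.DataFrame) -> SubjectSummary:
    """Condense a per-hour staging result to stay-level quantities."""
    if result.empty:
        raise ValueError("empty staging result")
    subject_id = str(result["subject_id"].iloc[0])
    overall = result["overall_stage"]
    defined = overall.notna()
    indeterminate = not defined.any()

    def first_hour(col: str) -> int | None:
        hit = result.loc[result[col].notna() & (result[col] >= 1), "hour_index"]
        return int(hit.iloc[0]) if len(hit) else None

    return SubjectSummary(
        subject_id=subject_id,
        max_overall_stage=None if indeterminate else int(overall.max()),
        first_aki_hour=first_hour("overall_stage"),
        first_stage_hour={col: first_hour(col) for col in STAGE_COLUMNS[:4]},
        hours_at_stage={
            s: int((overall == s).sum()) for s in range(4)
        },
        n_hours=len(result),
        n_undefined_hours=int((~defined).sum()),
        indeterminate=indeterminate,
    )


def write_staging_csv(staging: pd.DataFrame, path) -> None:
    """Write the staging table; undefined stages become empty fields."""
    staging.to_csv(path, index=False, columns=list(RESULT_COLUMNS))
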