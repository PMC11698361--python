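"""Declarative run configuration with full defaulting.

The defaults reproduce the validation setup: urine-output gaps of up to
6 h back-distributed, creatinine carried forward up to 72 h, the relative
creatinine criterion staged against a rolling 7-day (168 h) minimum and the
absolute criterion against a rolling 48-h minimum, strict anuria, assumed
GFR of 75 ml/min for the Cockcroft–Gault baseline.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import baselines
from .preprocessing import GapPolicy
from .probes import ProbeConfig

BaselineMethod = Literal[
    "fixed_window_min",
    "fixed_window_mean",
    "fixed_window_first",
    "rolling_window_min",
    "rolling_window_mean",
    "rolling_window_first",
    "constant",
    "expected_gfr",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessingConfig(_Strict):
    enabled: bool = True
    uo_max_gap_hours: int = 6
    scr_max_gap_hours: int = 72

    @model_validator(mode="after")
    def _check(self):
        GapPolicy(self.uo_max_gap_hours, self.scr_max_gap_hours)
        return self

    def gap_policy(self) -> GapPolicy:
        return GapPolicy(self.uo_max_gap_hours, self.scr_max_gap_hours)


class BaselineSpec(_Strict):
    method: BaselineMethod
    window_hours: int | None = None
    constant_value: float | None = None
    assumed_gfr: float = 75.0

    @model_validator(mode="after")
    def _check(self):
        if self.method.startswith(("fixed_window", "rolling_window")):
            if self.window_hours is None or self.window_hours < 1:
                raise ValueError(f"{self.method} requires window_hours >= 1")
        if self.method == "constant":
            if self.constant_value is None or self.constant_value <= 0:
                raise ValueError("constant baseline requires constant_value > 0")
        if self.assumed_gfr <= 0:
            raise ValueError("assumed_gfr must be > 0")
        return self


class BaselinesConfig(_Strict):
    relative: BaselineSpec = BaselineSpec(method="rolling_window_min", window_hours=168)
    absolute: BaselineSpec = BaselineSpec(method="rolling_window_min", window_hours=48)


class ProbesConfig(_Strict):
    anuria_threshold_ml_kg_h: float = 0.0
    epsilon: float = 1e-9

    @model_validator(mode="after")
    def _check(self):
        ProbeConfig(self.anuria_threshold_ml_kg_h, self.epsilon)
        return self

    def probe_config(self) -> ProbeConfig:
        return ProbeConfig(self.anuria_threshold_ml_kg_h, self.epsilon)


class PipelineConfig(_Strict):
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    baseline: BaselinesConfig = BaselinesConfig()
    probes: ProbesConfig = ProbesConfig()


def load_config(path) -> PipelineConfig:
    """Read a YAML configuration file; unknown keys are schema errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw or {})


def compute_baseline(
    scr: np.ndarray, spec: BaselineSpec, demographics: pd.Series | None = None
) -> np.ndarray:
    """Resolve a baseline spec into a per-hour reference creatinine series."""
    n = len(scr)
    if spec.method == "constant":
        return baselines.constant_baseline(spec.constant_value, n)
    if spec.method == "expected_gfr":
        if demographics is None:
            raise ValueError("expected_gfr baseline requires demographics")
        age = demographics.get("age_years")
        sex = demographics.get("sex")
        if pd.isna(age) or pd.isna(sex):
            raise ValueError("expected_gfr baseline requires age and sex")
        height = demographics.get("height_cm")
        value = baselines.expected_scr_from_gfr(
            float(age),
            float(demographics["weight_kg"]),
            str(sex),
            assumed_gfr=spec.assumed_gfr,
            height=None if pd.isna(height) else float(height),
        )
        return baselines.constant_baseline(value, n)
    mode, statistic = spec.method.rsplit("_", 1)
    mode = "fixed_start" if mode == "fixed_window" else "rolling"
    return baselines.window_baseline(scr, statistic, mode, spec.window_hours)
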