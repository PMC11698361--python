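"""Standardised input tables and the canonical hourly analysis frame.

The staging pipeline consumes three long-format measurement tables, each
keyed by ``subject_id`` and ``timestamp``:

* urine output — millilitres collected since the previous record,
* serum creatinine (SCr) — mg/dl,
* dialysis — boolean "renal replacement therapy active" status,

plus one demographics table (weight in kg is mandatory; height, age and sex
are needed only for the Cockcroft–Gault baseline). Everything downstream
operates on a contiguous per-subject hourly grid: hour 0 is the floor of the
subject's earliest observation across all three signals, and the grid runs
to the last observed hour. Timestamps are floored to the hour; collisions
within one hour are resolved by summing urine volumes, keeping the last
creatinine value and OR-ing dialysis flags.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: µmol/l of creatinine per mg/dl (molar mass of creatinine, 113.12 g/mol).
UMOL_L_PER_MG_DL = 88.42

# CSV schemas (header names are part of the public interface).
UO_COLUMNS = ("subject_id", "timestamp", "volume_ml")
SCR_COLUMNS = ("subject_id", "timestamp", "scr_mg_dl")
DIALYSIS_COLUMNS = ("subject_id", "timestamp", "active")
DEMOGRAPHICS_COLUMNS = ("subject_id", "weight_kg", "height_cm", "age_years", "sex")

STAGE_COLUMNS = (
    "uo_stage",
    "abs_scr_stage",
    "rel_scr_stage",
    "dialysis_stage",
    "overall_stage",
)
RESULT_COLUMNS = ("subject_id", "hour_index", "timestamp") + STAGE_COLUMNS


class SchemaError(ValueError):
    """A table does not conform to the expected CSV schema."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def convert_creatinine_units(value, unit: str):
    """Convert a creatinine concentration to mg/dl.

    Parameters
    ----------
    value : float or array-like
        Concentration, strictly positive.
    unit : {"mg_dl", "umol_l"}
        Unit of ``value``. SI creatinine (µmol/l) is divided by 88.42.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("creatinine must be > 0")
    if unit == "mg_dl":
        out = arr
    elif unit == "umol_l":
        out = arr / UMOL_L_PER_MG_DL
    else:
        raise ValueError(f"unknown creatinine unit {unit!r}; use 'mg_dl' or 'umol_l'")
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# CSV loading


def _read_measurements(path, value_col: str, table: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id", "timestamp", value_col), table)
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df


def load_urine_output(path) -> pd.DataFrame:
    return _read_measurements(path, "volume_ml", "urine_output")


def load_creatinine(path) -> pd.DataFrame:
    return _read_measurements(path, "scr_mg_dl", "creatinine")


def load_dialysis(path) -> pd.DataFrame:
    df = _read_measurements(path, "active", "dialysis")
    df["active"] = df["active"].astype(bool)
    return df


def load_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("subject_id", "weight_kg"), "demographics")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("height_cm", "age_years"):
        if col not in df.columns:
            df[col] = np.nan
    if "sex" not in df.columns:
        df["sex"] = pd.NA
    return df


# ---------------------------------------------------------------------------
# Input validation


@dataclasses.dataclass(frozen=True)
class Violation:
    table: str
    subject_id: str
    message: str
    hard: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        kind = "ERROR" if self.hard else "warning"
        return f"[{kind}] {self.table} / subject {self.subject_id}: {self.message}"


@dataclasses.dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def hard_violations(self) -> list[Violation]:
        return [v for v in self.violations if v.hard]

    @property
    def passed(self) -> bool:
        return not self.hard_violations


def validate_inputs(
    uo: pd.DataFrame,
    scr: pd.DataFrame,
    rrt: pd.DataFrame,
    demo: pd.DataFrame,
) -> ValidationReport:
    """Check the four input tables for structural violations.

    Hard violations (negative urine volumes, non-positive creatinine,
    subjects with measurements but no usable weight) make the report fail;
    soft violations (duplicate timestamps, paediatric age) are informative
    only. The report is deterministic regardless of input row order.
    """
    _require_columns(uo, UO_COLUMNS, "urine_output")
    _require_columns(scr, SCR_COLUMNS, "creatinine")
    _require_columns(rrt, DIALYSIS_COLUMNS, "dialysis")
    _require_columns(demo, ("subject_id", "weight_kg"), "demographics")

    out: list[Violation] = []

    for sid in sorted(uo.loc[uo["volume_ml"] < 0, "subject_id"].astype(str).unique()):
        out.append(Violation("urine_output", sid, "negative volume", hard=True))
    for sid in sorted(scr.loc[scr["scr_mg_dl"] <= 0, "subject_id"].astype(str).unique()):
        out.append(Violation("creatinine", sid, "non-positive creatinine", hard=True))

    for name, table in (("urine_output", uo), ("creatinine", scr), ("dialysis", rrt)):
        dup = table.duplicated(subset=["subject_id", "timestamp"], keep=False)
        for sid in sorted(table.loc[dup, "subject_id"].astype(str).unique()):
            out.append(
                Violation(name, sid, "duplicate timestamps (will be collapsed)", hard=False)
            )

    measured = (
        set(uo["subject_id"].astype(str))
        | set(scr["subject_id"].astype(str))
        | set(rrt["subject_id"].astype(str))
    )
    demo_idx = demo.set_index(demo["subject_id"].astype(str))
    for sid in sorted(measured):
        if sid not in demo_idx.index:
            out.append(
                Violation("demographics", sid, "subject has measurements but no demographics row", hard=True)
            )
            continue
        row = demo_idx.loc[sid]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        weight = row.get("weight_kg")
        if pd.isna(weight) or float(weight) <= 0:
            out.append(Violation("demographics", sid, "missing or non-positive weight", hard=True))
        age = row.get("age_years")
        if not pd.isna(age) and float(age) < 18:
            out.append(
                Violation("demographics", sid, "age < 18: paediatric staging unsupported", hard=False)
            )

    out.sort(key=lambda v: (v.table, v.subject_id, v.message))
    return ValidationReport(out)


# ---------------------------------------------------------------------------
# Hourly grid construction


def floor_to_hour(ts: pd.Series) -> pd.Series:
    return pd.to_datetime(ts).dt.floor("h")


def collapse_hourly(df: pd.DataFrame, value_col: str, how: str) -> pd.DataFrame:
    """Floor timestamps to the hour and resolve intra-hour collisions.

    ``how`` is ``"sum"`` (urine volumes), ``"last"`` (creatinine: latest
    value within the hour wins) or ``"any"`` (dialysis flags OR-ed).
    Returns a frame with columns ``hour`` (Timestamp) and ``value_col``,
    sorted by hour, one row per hour.
    """
    if df.empty:
        return pd.DataFrame({"hour": pd.Series([], dtype="datetime64[ns]"), value_col: []})
    work = df.sort_values("timestamp", kind="stable").copy()
    work["hour"] = floor_to_hour(work["timestamp"])
    grouped = work.groupby("hour", sort=True)[value_col]
    if how == "sum":
        collapsed = grouped.sum()
    elif how == "last":
        collapsed = grouped.last()
    elif how == "any":
        collapsed = grouped.any()
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"unknown collapse rule {how!r}")
    return collapsed.reset_index()


@dataclasses.dataclass
class HourlyFrame:
    """Per-subject contiguous hourly grid — the canonical probe input.

    ``uo_ml`` and ``scr`` use NaN for missing hours; ``dialysis`` is a dense
    boolean array (inactive where nothing was recorded). ``anchor`` is the
    wall-clock hour of ``hour_index`` 0.
    """

    subject_id: str
    anchor: pd.Timestamp
    uo_ml: np.ndarray
    scr: np.ndarray
    dialysis: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        self.uo_ml = np.asarray(self.uo_ml, dtype=float)
        self.scr = np.asarray(self.scr, dtype=float)
        self.dialysis = np.asarray(self.dialysis, dtype=bool)
        n = len(self.uo_ml)
        if len(self.scr) != n or len(self.dialysis) != n:
            raise ValueError("hourly series must share one length")
        if np.any(self.uo_ml[~np.isnan(self.uo_ml)] < 0):
            raise ValueError("urine output must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")

    @property
    def n_hours(self) -> int:
        return len(self.uo_ml)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.anchor + pd.to_timedelta(np.arange(self.n_hours), unit="h")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "hour_index": np.arange(self.n_hours),
                "timestamp": self.timestamps,
                "uo_ml": self.uo_ml,
                "scr": self.scr,
                "dialysis": self.dialysis,
                "weight": self.weight,
            }
        )


def grid_span(collapsed: Mapping[str, pd.DataFrame]) -> tuple[pd.Timestamp, int]:
    """Anchor hour and grid length covering all collapsed tables.

    ``collapsed`` maps a signal name to a frame with an ``hour`` column (as
    produced by :func:`collapse_hourly`); empty frames are ignored.
    """
    hours = [df["hour"] for df in collapsed.values() if not df.empty]
    if not hours:
        raise ValueError("subject has no observations in any table")
    first = min(h.min() for h in hours)
    last = max(h.max() for h in hours)
    n = int((last - first) / pd.Timedelta(hours=1)) + 1
    return first, n


def hour_indices(collapsed: pd.DataFrame, anchor: pd.Timestamp) -> np.ndarray:
    """Integer grid positions of a collapsed table's hours."""
    if collapsed.empty:
        return np.array([], dtype=int)
    delta = (collapsed["hour"] - anchor) / pd.Timedelta(hours=1)
    return delta.to_numpy().astype(int)
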