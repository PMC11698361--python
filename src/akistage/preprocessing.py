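"""Up-sampling of sparse raw records to the contiguous hourly grid.

Two imputation rules only:

* urine output: a recorded bag volume is spread evenly over the hours since
  the previous record (back-distribution), as long as the span does not
  exceed a configurable gap limit;
* creatinine: last observation carried forward, up to a gap limit.

Beyond a gap limit the affected hours stay missing, and the staging probes
restart their windows after the gap. Hours that were never observed are
missing, never zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass(frozen=True)
class GapPolicy:
    """Interpolation limits, in hours.

    ``uo_max_gap``: longest record-to-record span over which a urine volume
    is still back-distributed (spans of exactly the limit are filled).
    ``scr_max_gap``: how many hours past a creatinine draw the value is
    carried forward when no newer draw arrives.
    """

    uo_max_gap: int = 6
    scr_max_gap: int = 72

    def __post_init__(self) -> None:
        if self.uo_max_gap < 1 or self.scr_max_gap < 1:
            raise ValueError("gap limits must be >= 1 hour")


def distribute_urine_output(
    hours: np.ndarray, volumes: np.ndarray, n_hours: int, policy: GapPolicy = GapPolicy()
) -> np.ndarray:
    """Back-distribute recorded urine volumes onto the hourly grid.

    ``hours`` are strictly increasing grid indices (hour-floored, intra-hour
    volumes already summed) and ``volumes`` the matching millilitres. Each
    volume is divided equally over the hours from (exclusive) the previous
    record's hour to (inclusive) its own; a span exceeding
    ``policy.uo_max_gap`` leaves the intermediate hours missing and the
    record's own hour carries the full volume. The first record of a stay
    has no predecessor and is assigned to its own hour only.

    The sum over any fully distributed span equals the recorded volume
    exactly: hourly shares are consecutive differences of the cumulative
    fractions ``volume * (i / span)``, which telescope to the recorded
    volume under IEEE arithmetic while staying equal to within an ulp.
    """
    hours = np.asarray(hours, dtype=int)
    volumes = np.asarray(volumes, dtype=float)
    out = np.full(n_hours, np.nan)
    if hours.size == 0:
        return out
    if np.any(np.diff(hours) <= 0):
        raise ValueError("record hours must be strictly increasing")
    if hours[0] < 0 or hours[-1] >= n_hours:
        raise ValueError("record hours outside the grid")

    out[hours[0]] = volumes[0]
    for prev, h, v in zip(hours[:-1], hours[1:], volumes[1:]):
        span = h - prev
        if span <= policy.uo_max_gap:
            edges = v * (np.arange(span + 1) / span)
            out[prev + 1 : h + 1] = np.diff(edges)
        else:
            out[h] = v
    return out


def carry_forward_creatinine(
    hours: np.ndarray, values: np.ndarray, n_hours: int, policy: GapPolicy = GapPolicy()
) -> np.ndarray:
    """Carry each creatinine draw forward on the hourly grid.

    An observed value fills its own hour and subsequent hours until the next
    draw, or until ``policy.scr_max_gap`` hours have elapsed since the draw,
    whichever comes first. Hours beyond the limit stay missing. Hours before
    the first draw are missing.
    """
    hours = np.asarray(hours, dtype=int)
    values = np.asarray(values, dtype=float)
    out = np.full(n_hours, np.nan)
    if hours.size == 0:
        return out
    if np.any(np.diff(hours) <= 0):
        raise ValueError("record hours must be strictly increasing")
    if hours[0] < 0 or hours[-1] >= n_hours:
        raise ValueError("record hours outside the grid")

    nxt = np.append(hours[1:], n_hours)
    for h, v, stop in zip(hours, values, nxt):
        end = min(stop - 1, h + policy.scr_max_gap, n_hours - 1)
        out[h : end + 1] = v
    return out


def expand_dialysis(hours: np.ndarray, active: np.ndarray, n_hours: int) -> np.ndarray:
    """Expand sparse dialysis status records to a dense hourly boolean series.

    The last recorded state is carried forward indefinitely; hours before
    the first record are inactive.
    """
    hours = np.asarray(hours, dtype=int)
    active = np.asarray(active, dtype=bool)
    out = np.zeros(n_hours, dtype=bool)
    if hours.size == 0:
        return out
    if np.any(np.diff(hours) <= 0):
        raise ValueError("record hours must be strictly increasing")
    if hours[0] < 0 or hours[-1] >= n_hours:
        raise ValueError("record hours outside the grid")

    nxt = np.append(hours[1:], n_hours)
    for h, v, stop in zip(hours, active, nxt):
        out[h:stop] = v
    return out


def place_without_imputation(
    hours: np.ndarray, values: np.ndarray, n_hours: int, fill=np.nan
) -> np.ndarray:
    """Place records on the grid verbatim — the imputation-free path."""
    hours = np.asarray(hours, dtype=int)
    dtype = bool if isinstance(fill, (bool, np.bool_)) else float
    out = np.full(n_hours, fill, dtype=dtype)
    out[hours] = np.asarray(values, dtype=dtype)
    return out
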