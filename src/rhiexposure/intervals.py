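"""Real inter-impact time intervals from game-clock stamps.

The game clock runs for 60 minutes but a professional game takes roughly
three hours of wall-clock time, so clock differences between impacts are
multiplied by a per-game *stop factor* (broadcast duration / clock playing
time).  Fixed wall-clock paddings are then added where an impact pair
straddles a break: 2 minutes at the Q1/Q2 and Q3/Q4 breaks, 12 minutes at
halftime, 5 minutes between regulation and overtime.  Real intervals are
binned into four ordinal categories whose weights (4 down to 1: shorter
interval, higher weight) enter the BSE/T exposure index.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .impact_log import ClockStamp, GameLog, GameMeta, ImpactEvent
from .strain_map import MagnitudeCategory

__all__ = [
    "IntervalCategory",
    "INTERVAL_BOUNDS_MIN",
    "GameTimeline",
    "stop_factor",
    "clock_elapsed",
    "real_intervals",
    "arrival_times",
    "categorize_interval",
    "per_magnitude_intervals",
    "intervals_frame",
]


class IntervalCategory(enum.IntEnum):
    """Ordinal inter-impact interval category (1 = shortest intervals)."""

    VERY_LOW = 1  # < 15 min
    LOW = 2  # [15, 31) min
    MODERATE = 3  # [31, 91) min
    HIGH = 4  # >= 91 min

    @property
    def weight(self) -> int:
        """BSE/T interval weight: 4 for the shortest intervals down to 1."""
        return 5 - int(self)

    @property
    def bounds_min(self) -> tuple:
        edges = (0.0,) + INTERVAL_BOUNDS_MIN + (math.inf,)
        return edges[self - 1], edges[self]


#: Interior bounds (minutes) of the four interval categories; half-open:
#: [0,15), [15,31), [31,91), [91,inf).
INTERVAL_BOUNDS_MIN = (15.0, 31.0, 91.0)


def categorize_interval(minutes: float) -> IntervalCategory:
    if minutes < 0:
        raise ValueError(f"interval must be non-negative, got {minutes}")
    return IntervalCategory(bisect_right(INTERVAL_BOUNDS_MIN, minutes) + 1)


@dataclass(frozen=True)
class GameTimeline:
    """Clock structure of a game: quarter and overtime period lengths."""

    quarter_length_min: float = 15.0
    ot_length_min: float = 15.0

    #: wall-clock paddings (minutes) added when an interval straddles a break
    quarter_break_min: float = 2.0
    halftime_min: float = 12.0
    overtime_break_min: float = 5.0

    def period_length(self, quarter: int) -> float:
        return self.quarter_length_min if quarter <= 4 else self.ot_length_min

    def break_padding(self, quarter_before: int) -> float:
        """Wall-clock padding for the break after the given quarter."""
        if quarter_before == 2:
            return self.halftime_min
        if quarter_before in (1, 3):
            return self.quarter_break_min
        return self.overtime_break_min  # regulation -> OT, or between OTs


DEFAULT_TIMELINE = GameTimeline()


def stop_factor(meta: GameMeta) -> float:
    """Real-time minutes elapsing per game-clock minute for one game."""
    if meta.clock_duration_min <= 0:
        raise ValueError("clock_duration_min must be > 0")
    return meta.broadcast_duration_min / meta.clock_duration_min


def clock_elapsed(a: ClockStamp, b: ClockStamp, timeline: GameTimeline = DEFAULT_TIMELINE) -> float:
    """Game-clock minutes elapsed from stamp ``a`` to the later stamp ``b``."""
    if b.sort_key() < a.sort_key():
        raise ValueError(f"stamp {b} is earlier than {a}")
    if a.quarter == b.quarter:
        return a.clock_remaining_min - b.clock_remaining_min
    elapsed = a.clock_remaining_min  # remainder of a's quarter
    for q in range(a.quarter + 1, b.quarter):
        elapsed += timeline.period_length(q)
    elapsed += timeline.period_length(b.quarter) - b.clock_remaining_min
    return elapsed


def _pad_between(a: ClockStamp, b: ClockStamp, timeline: GameTimeline) -> float:
    return sum(timeline.break_padding(q) for q in range(a.quarter, b.quarter))


def real_intervals(
    log: Union[GameLog, Sequence[ImpactEvent]],
    meta: Optional[GameMeta] = None,
    timeline: GameTimeline = DEFAULT_TIMELINE,
    first_impact: str = "kickoff",
) -> np.ndarray:
    """Real-time minutes since the previous impact, per impact.

    Each clock difference is multiplied by the game's stop factor; break
    paddings (already wall-clock) are added afterwards.  The first impact's
    interval is measured from kickoff under the same rules (default), or set
    to NaN with ``first_impact='exclude'`` so it drops out of
    interval-weighted scoring.  Results are also written onto each impact's
    ``interval_min`` / ``interval_cat`` fields.
    """
    if first_impact not in ("kickoff", "exclude"):
        raise ValueError(f"unknown first_impact mode {first_impact!r}")
    if isinstance(log, GameLog):
        impacts = log.impacts
        meta = meta if meta is not None else log.meta
    else:
        impacts = list(log)
    if meta is None:
        raise ValueError("real_intervals requires game metadata for the stop factor")
    keys = [ev.stamp.sort_key() for ev in impacts]
    if keys != sorted(keys):
        raise ValueError("impacts must be chronologically sorted")
    factor = stop_factor(meta)
    out = np.full(len(impacts), np.nan)
    kickoff = ClockStamp(1, timeline.quarter_length_min)
    prev: Optional[ClockStamp] = kickoff if first_impact == "kickoff" else None
    for i, ev in enumerate(impacts):
        if prev is not None:
            minutes = (
                clock_elapsed(prev, ev.stamp, timeline) * factor
                + _pad_between(prev, ev.stamp, timeline)
            )
            out[i] = minutes
            ev.interval_min = minutes
            ev.interval_cat = categorize_interval(minutes)
        else:
            ev.interval_min = None
            ev.interval_cat = None
        prev = ev.stamp
    return out


def arrival_times(
    log: Union[GameLog, Sequence[ImpactEvent]],
    meta: Optional[GameMeta] = None,
    timeline: GameTimeline = DEFAULT_TIMELINE,
) -> np.ndarray:
    """Real-time minutes from kickoff to each impact (cumulative intervals)."""
    gaps = real_intervals(log, meta, timeline, first_impact="kickoff")
    return np.cumsum(gaps)


def per_magnitude_intervals(
    log: Union[GameLog, Sequence[ImpactEvent]],
    meta: Optional[GameMeta] = None,
    timeline: GameTimeline = DEFAULT_TIMELINE,
    min_impacts: int = 3,
) -> dict:
    """Mean real interval between same-magnitude impacts within one game.

    For each magnitude category, the mean of the gaps between consecutive
    impacts of that category (in real time), computed only when the game
    contains more than two impacts of the category; otherwise ``None``
    (not computable).  Impacts must already carry magnitude assignments.
    """
    impacts = log.impacts if isinstance(log, GameLog) else list(log)
    times = arrival_times(impacts, meta if meta is not None else getattr(log, "meta", None), timeline)
    out = {cat: None for cat in MagnitudeCategory}
    for cat in MagnitudeCategory:
        ts = [t for t, ev in zip(times, impacts) if ev.magnitude == cat]
        if len(ts) >= min_impacts:
            gaps = np.diff(sorted(ts))
            out[cat] = float(np.mean(gaps))
    return out


def intervals_frame(logs: Sequence[GameLog], **kwargs) -> pd.DataFrame:
    """Per-impact interval audit table (game_id, impact_index, interval, category)."""
    rows = []
    for log in logs:
        real_intervals(log, **kwargs)
        for i, ev in enumerate(log):
            rows.append(
                {
                    "game_id": ev.game_id,
                    "impact_index": i,
                    "position": ev.position.value,
                    "interval_min": ev.interval_min,
                    "interval_cat": ev.interval_cat.name.lower() if ev.interval_cat else "",
                }
            )
    return pd.DataFrame(rows, columns=["game_id", "impact_index", "position", "interval_min", "interval_cat"])
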