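"""Data model, I/O, validation and frequency reporting for head-impact logs.

One row of a log is a single documented head impact observed on game film:
which position sustained it, what struck the head (event type), where on the
helmet, whether the impact could be confirmed, and the game-clock time at
which it occurred.  A :class:`GameLog` bundles the impacts of one game with
the timing metadata needed for stop-time correction.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlayerPosition",
    "EventKind",
    "PRIMARY_EVENT_KINDS",
    "ImpactStatus",
    "ClockStamp",
    "ImpactEvent",
    "GameMeta",
    "GameLog",
    "SchemaError",
    "RowError",
    "read_game_log",
    "read_game_logs",
    "read_game_meta",
    "write_game_log",
    "write_game_meta",
    "select_analysis_set",
    "frequency_summary",
    "career_projection",
]


class SchemaError(ValueError):
    """The input file does not conform to the documented column schema."""


class RowError(ValueError):
    """A single row of an input file could not be parsed or validated."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class PlayerPosition(str, enum.Enum):
    """The eight American-style-football field positions tracked."""

    QB = "QB"
    RB = "RB"
    WR = "WR"
    TE = "TE"
    OL = "OL"
    DL = "DL"
    LB = "LB"
    DB = "DB"


class EventKind(str, enum.Enum):
    """What struck the player's head.

    The four primary kinds (helmet, shoulder, hip/thigh, ground) are the
    only strain-scorable events; everything else is ``other`` with a free
    text sublabel (back, chest, arm, ...).
    """

    HELMET = "helmet"
    SHOULDER = "shoulder"
    HIP_THIGH = "hip_thigh"
    GROUND = "ground"
    OTHER = "other"


PRIMARY_EVENT_KINDS = frozenset(
    {EventKind.HELMET, EventKind.SHOULDER, EventKind.HIP_THIGH, EventKind.GROUND}
)


class ImpactStatus(str, enum.Enum):
    """Review outcome for a documented impact.

    ``confirmed``: head contact clearly visible, event type and head
    location determinable.  ``suspected``: an impact likely occurred but
    could not be confirmed (video quality, camera angle, occlusion).
    ``multiple``: a pile-up in which several impacts are suspected but none
    can be individually characterized.
    """

    CONFIRMED = "confirmed"
    SUSPECTED = "suspected"
    MULTIPLE = "multiple"


#: Quarter index used for overtime.  Quarters 1-4 are regulation.
OVERTIME_QUARTER = 5

_CLOCK_RE = re.compile(r"^(\d{1,2}):([0-5]\d(?:\.\d+)?)$")


@dataclass(frozen=True, order=True)
class ClockStamp:
    """A game-clock timestamp: quarter plus minutes remaining (counts down)."""

    quarter: int
    clock_remaining_min: float

    def __post_init__(self):
        if self.quarter < 1:
            raise ValueError(f"quarter must be >= 1, got {self.quarter}")
        if not 0.0 <= self.clock_remaining_min <= 60.0:
            raise ValueError(
                f"clock_remaining_min out of range: {self.clock_remaining_min}"
            )

    @property
    def is_overtime(self) -> bool:
        return self.quarter >= OVERTIME_QUARTER

    @classmethod
    def parse(cls, quarter: Union[int, str], clock: Union[str, float]) -> "ClockStamp":
        """Parse a quarter label (1-4 or 'OT') and an 'MM:SS' clock reading."""
        if isinstance(quarter, str):
            q = quarter.strip().upper()
            if q.startswith("OT"):
                extra = q[2:]
                quarter_i = OVERTIME_QUARTER + (int(extra) - 1 if extra else 0)
            else:
                quarter_i = int(q.lstrip("Q") or q)
        else:
            quarter_i = int(quarter)
        if isinstance(clock, str):
            m = _CLOCK_RE.match(clock.strip())
            if m is None:
                raise ValueError(f"unparseable clock stamp {clock!r} (expected MM:SS)")
            minutes = int(m.group(1)) + float(m.group(2)) / 60.0
        else:
            minutes = float(clock)
        return cls(quarter_i, minutes)

    def format_clock(self) -> str:
        whole = int(self.clock_remaining_min)
        seconds = round((self.clock_remaining_min - whole) * 60.0)
        if seconds == 60:  # float round-up at the minute boundary
            whole, seconds = whole + 1, 0
        return f"{whole:02d}:{seconds:02d}"

    def quarter_label(self) -> str:
        if self.quarter < OVERTIME_QUARTER:
            return str(self.quarter)
        n = self.quarter - OVERTIME_QUARTER + 1
        return "OT" if n == 1 else f"OT{n}"

    def sort_key(self):
        # chronological: quarter ascending, clock counting DOWN within it
        return (self.quarter, -self.clock_remaining_min)


@dataclass
class ImpactEvent:
    """One documented head impact."""

    game_id: str
    position: PlayerPosition
    player_ref: str
    event: Optional[EventKind]
    status: ImpactStatus
    stamp: ClockStamp
    event_sublabel: Optional[str] = None
    head_location: Optional[str] = None
    elevation_level: Optional[int] = None
    velocity_mps: Optional[float] = None
    velocity_level: Optional[object] = None  # kinematics.VelocityLevel
    mps_percent: Optional[float] = None
    magnitude: Optional[object] = None  # strain_map.MagnitudeCategory
    interval_min: Optional[float] = None
    interval_cat: Optional[object] = None  # intervals.IntervalCategory
    pile_count: Optional[int] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = PlayerPosition(self.position)
        if self.event is not None:
            self.event = EventKind(self.event)
        self.status = ImpactStatus(self.status)
        if self.status is ImpactStatus.CONFIRMED:
            if self.event is None:
                raise ValueError("confirmed impact requires an event type")
            if self.head_location is None:
                raise ValueError("confirmed impact requires a head location")
        if self.event is EventKind.OTHER and not self.event_sublabel:
            raise ValueError("event kind 'other' requires event_sublabel")
        if self.event is not None and self.event is not EventKind.OTHER and self.event_sublabel:
            raise ValueError("event_sublabel is only valid for event kind 'other'")
        if self.velocity_mps is not None and self.velocity_mps < 0:
            raise ValueError("velocity_mps must be non-negative")
        if self.mps_percent is not None and not 0.0 <= self.mps_percent <= 100.0:
            raise ValueError(f"mps_percent out of [0, 100]: {self.mps_percent}")
        if self.pile_count is not None:
            if self.status is not ImpactStatus.MULTIPLE:
                raise ValueError("pile_count is only valid for status 'multiple'")
            if self.pile_count < 1:
                raise ValueError("pile_count must be >= 1")
        if self.elevation_level is not None and not 1 <= self.elevation_level <= 5:
            raise ValueError(f"elevation_level out of 1-5: {self.elevation_level}")

    @property
    def is_confirmed_primary(self) -> bool:
        return (
            self.status is ImpactStatus.CONFIRMED
            and self.event in PRIMARY_EVENT_KINDS
        )


@dataclass(frozen=True)
class GameMeta:
    """Timing metadata for one game, used for stop-time correction."""

    game_id: str
    broadcast_duration_min: float
    clock_duration_min: float
    has_overtime: bool = False

    def __post_init__(self):
        if self.clock_duration_min <= 0:
            raise ValueError("clock_duration_min must be > 0")
        if self.broadcast_duration_min < self.clock_duration_min:
            raise ValueError(
                "broadcast_duration_min must be >= clock_duration_min "
                f"({self.broadcast_duration_min} < {self.clock_duration_min})"
            )


@dataclass
class GameLog:
    """All impacts tracked for one game, chronologically sorted."""

    meta: Optional[GameMeta]
    impacts: list = field(default_factory=list)

    def __post_init__(self):
        # stable sort: simultaneous stamps keep input (file) order
        self.impacts = sorted(self.impacts, key=lambda e: e.stamp.sort_key())

    @property
    def game_id(self) -> Optional[str]:
        if self.meta is not None:
            return self.meta.game_id
        return self.impacts[0].game_id if self.impacts else None

    def __len__(self) -> int:
        return len(self.impacts)

    def __iter__(self):
        return iter(self.impacts)


# ---------------------------------------------------------------------------
# serialization

#: Documented column schema for impact logs (CSV header / JSON record keys).
LOG_COLUMNS = [
    "game_id",
    "position",
    "player",
    "event_type",
    "event_sublabel",
    "head_location",
    "elevation_level",
    "status",
    "quarter",
    "clock_remaining",
    "velocity_mps",
    "pile_count",
]

_MANDATORY = [
    "game_id",
    "position",
    "player",
    "event_type",
    "status",
    "quarter",
    "clock_remaining",
]

META_COLUMNS = ["game_id", "broadcast_duration_min", "clock_duration_min", "has_overtime"]


def _is_na(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _load_records(source) -> pd.DataFrame:
    path = Path(source)
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            records = json.load(fh)
        return pd.DataFrame.from_records(records)
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _row_to_event(idx: int, row: Mapping) -> ImpactEvent:
    try:
        stamp = ClockStamp.parse(row["quarter"], row["clock_remaining"])
    except (ValueError, TypeError) as exc:
        raise RowError(idx, str(exc)) from exc
    known = set(LOG_COLUMNS)
    annotations = {k: v for k, v in row.items() if k not in known and not _is_na(v)}
    try:
        return ImpactEvent(
            game_id=str(row["game_id"]),
            position=PlayerPosition(str(row["position"]).strip().upper()),
            player_ref=str(row["player"]),
            event=None if _is_na(row["event_type"]) else EventKind(str(row["event_type"]).strip()),
            event_sublabel=None if _is_na(row.get("event_sublabel")) else str(row["event_sublabel"]),
            head_location=None if _is_na(row.get("head_location")) else str(row["head_location"]).strip(),
            elevation_level=None if _is_na(row.get("elevation_level")) else int(float(row["elevation_level"])),
            status=ImpactStatus(str(row["status"]).strip().lower()),
            stamp=stamp,
            velocity_mps=None if _is_na(row.get("velocity_mps")) else float(row["velocity_mps"]),
            pile_count=None if _is_na(row.get("pile_count")) else int(float(row["pile_count"])),
            annotations=annotations,
        )
    except RowError:
        raise
    except (ValueError, KeyError) as exc:
        raise RowError(idx, str(exc)) from exc


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")


def read_game_log(source, meta: Optional[GameMeta] = None) -> GameLog:
    """Read a single-game impact log from CSV or JSON.

    The file must contain the documented columns; unknown columns are kept
    as per-impact annotations.  Rows are sorted chronologically (quarter
    ascending, clock counting down; ties keep file order).
    """
    df = _load_records(source)
    if len(df) == 0:
        if not set(_MANDATORY) <= set(df.columns):
            _check_schema(df)
        return GameLog(meta=meta, impacts=[])
    _check_schema(df)
    events = [_row_to_event(i, row) for i, row in enumerate(df.to_dict("records"))]
    game_ids = {e.game_id for e in events}
    if len(game_ids) > 1:
        raise SchemaError(
            f"read_game_log expects one game per file, found game_ids {sorted(game_ids)}; "
            "use read_game_logs for multi-game files"
        )
    return GameLog(meta=meta, impacts=events)


def read_game_logs(source, meta_source=None) -> list:
    """Read a multi-game impact log, splitting on the ``game_id`` column."""
    df = _load_records(source)
    _check_schema(df)
    metas = read_game_meta(meta_source) if meta_source is not None else {}
    events = [_row_to_event(i, row) for i, row in enumerate(df.to_dict("records"))]
    by_game: dict = {}
    for ev in events:
        by_game.setdefault(ev.game_id, []).append(ev)
    return [
        GameLog(meta=metas.get(gid), impacts=evs) for gid, evs in by_game.items()
    ]


def read_game_meta(source) -> dict:
    """Read game metadata (CSV or JSON) into a ``{game_id: GameMeta}`` map."""
    df = _load_records(source)
    missing = [c for c in META_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    out = {}
    for i, row in enumerate(df.to_dict("records")):
        try:
            ot = row.get("has_overtime", False)
            if isinstance(ot, str):
                ot = ot.strip().lower() in {"1", "true", "yes"}
            out[str(row["game_id"])] = GameMeta(
                game_id=str(row["game_id"]),
                broadcast_duration_min=float(row["broadcast_duration_min"]),
                clock_duration_min=float(row["clock_duration_min"]),
                has_overtime=bool(ot),
            )
        except (ValueError, KeyError) as exc:
            raise RowError(i, str(exc)) from exc
    return out


def _event_to_row(ev: ImpactEvent) -> dict:
    row = {
        "game_id": ev.game_id,
        "position": ev.position.value,
        "player": ev.player_ref,
        "event_type": "" if ev.event is None else ev.event.value,
        "event_sublabel": ev.event_sublabel or "",
        "head_location": ev.head_location or "",
        "elevation_level": "" if ev.elevation_level is None else ev.elevation_level,
        "status": ev.status.value,
        "quarter": ev.stamp.quarter_label(),
        "clock_remaining": ev.stamp.format_clock(),
        "velocity_mps": "" if ev.velocity_mps is None else repr(ev.velocity_mps),
        "pile_count": "" if ev.pile_count is None else ev.pile_count,
    }
    row.update(ev.annotations)
    return row


def write_game_log(logs, path) -> None:
    """Write one log or a collection of logs to CSV (or JSON by suffix)."""
    if isinstance(logs, GameLog):
        logs = [logs]
    rows = [_event_to_row(ev) for log in logs for ev in log]
    extra = sorted({k for r in rows for k in r} - set(LOG_COLUMNS))
    df = pd.DataFrame(rows, columns=LOG_COLUMNS + extra)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
    else:
        df.to_csv(path, index=False)


def write_game_meta(metas: Iterable[GameMeta], path) -> None:
    rows = [
        {
            "game_id": m.game_id,
            "broadcast_duration_min": m.broadcast_duration_min,
            "clock_duration_min": m.clock_duration_min,
            "has_overtime": m.has_overtime,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis-set selection & frequency reporting

def select_analysis_set(log: Union[GameLog, Sequence[ImpactEvent]]) -> list:
    """Confirmed impacts of the four primary event types, order preserved.

    Only these impacts enter strain, interval and BSE/T scoring; suspected
    and pile-up impacts are reported separately.
    """
    impacts = log.impacts if isinstance(log, GameLog) else list(log)
    return [ev for ev in impacts if ev.is_confirmed_primary]


def frequency_summary(
    logs: Sequence[GameLog], games_per_season: int = 16
) -> pd.DataFrame:
    """Per-position head-impact frequency table across a set of games.

    Every game is assumed to track all positions (the study design: one
    starter per position per game), so a position absent from a game
    contributes a zero count for that game.  Positions with no impacts in
    any game are omitted with a warning, since an untracked position is
    indistinguishable from a tracked one that was never hit.

    Returns a DataFrame indexed by position code with columns:
    ``total_confirmed, games, per_game_mean, per_game_sd, per_season,
    suspected, pile_ups`` (means/SDs/season estimates rounded to 1 decimal
    as in standard reporting; ``per_season`` is the unrounded per-game mean
    times ``games_per_season``, then rounded to 1 decimal).
    """
    n_games = len(logs)
    if n_games == 0:
        raise ValueError("frequency_summary requires at least one game log")
    counts = {p: [0] * n_games for p in PlayerPosition}
    suspected = {p: 0 for p in PlayerPosition}
    pile_ups = {p: 0 for p in PlayerPosition}
    for gi, log in enumerate(logs):
        for ev in log:
            if ev.status is ImpactStatus.CONFIRMED:
                counts[ev.position][gi] += 1
            elif ev.status is ImpactStatus.SUSPECTED:
                suspected[ev.position] += 1
            else:
                pile_ups[ev.position] += 1
    rows = []
    for pos in PlayerPosition:
        per_game = counts[pos]
        total = sum(per_game)
        if total == 0 and suspected[pos] == 0 and pile_ups[pos] == 0:
            logger.warning("position %s has no impacts in any game; omitted", pos.value)
            continue
        mean = total / n_games
        if n_games > 1:
            var = sum((c - mean) ** 2 for c in per_game) / (n_games - 1)
            sd = math.sqrt(var)
        else:
            sd = 0.0
        rows.append(
            {
                "position": pos.value,
                "total_confirmed": total,
                "games": n_games,
                "per_game_mean": round(mean, 1),
                "per_game_sd": round(sd, 1),
                "per_season": round(mean * games_per_season, 1),
                "suspected": suspected[pos],
                "pile_ups": pile_ups[pos],
            }
        )
    return pd.DataFrame(rows).set_index("position")


def career_projection(
    per_game_mean: float,
    per_season: float,
    avg_years: float,
    record_games: int,
) -> tuple:
    """Project a player's career head-impact count two ways.

    ``estimate_avg_career`` extrapolates the per-season estimate over an
    average professional career length (rounded to the nearest impact);
    ``estimate_record`` extrapolates the per-game mean over the greatest
    number of games ever played (1 decimal).
    """
    for name, v in [
        ("per_game_mean", per_game_mean),
        ("per_season", per_season),
        ("avg_years", avg_years),
        ("record_games", record_games),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    estimate_avg_career = int(round(per_season * avg_years))
    estimate_record = round(per_game_mean * record_games, 1)
    return estimate_avg_career, estimate_record
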