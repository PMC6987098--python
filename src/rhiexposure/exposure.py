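"""The BSE/T cumulative exposure index and its aggregation.

BSE/T (brain strain exposure per time) condenses one position-game's
repetitive head impact exposure into a single number: each confirmed
primary-type impact contributes the product of its strain-magnitude severity
weight (1-5) and its inter-impact interval weight (4 for the shortest
intervals down to 1), and the per-magnitude-category sums are added and
divided by the total impact count.  The index is therefore a
frequency-normalized mean of severity x recency and is bounded in [1, 20]
for any non-empty game.

Two weighting modes are exposed.  The default ``per_impact`` mode weights
every impact by its own interval category.  The ``category_mean`` mode is
the literal five-term reading: each magnitude category's frequency is
multiplied by its severity and by the interval weight of the *mean* interval
of that category's impacts.  The modes agree whenever all impacts of each
magnitude category share one interval category.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .impact_log import (
    GameLog,
    GameMeta,
    ImpactEvent,
    ImpactStatus,
    PlayerPosition,
    select_analysis_set,
)
from .intervals import (
    DEFAULT_TIMELINE,
    GameTimeline,
    categorize_interval,
    real_intervals,
)
from .strain_map import ExemplarTable, MagnitudeCategory, assign_mps, bundled_default_table

logger = logging.getLogger(__name__)

__all__ = [
    "BSET_MODES",
    "UndefinedIndexError",
    "compute_bset",
    "ExposureRecord",
    "game_exposure",
    "season_aggregate",
    "ProfileSummary",
    "DEFAULT_PROFILE_MEMBERSHIP",
    "OVERLAPPING_POSITIONS",
    "profile_report",
    "records_frame",
]

BSET_MODES = ("per_impact", "category_mean")


class UndefinedIndexError(ValueError):
    """BSE/T is undefined for an empty impact set (0 is outside [1, 20])."""


def compute_bset(impacts: Sequence[ImpactEvent], mode: str = "per_impact") -> float:
    """Compute the BSE/T index over one position-game's analysis set.

    Every impact must carry a magnitude category and (per-impact mode) an
    interval category, or (category-mean mode) an interval in minutes.
    Raises :class:`UndefinedIndexError` on empty input.
    """
    if mode not in BSET_MODES:
        raise ValueError(f"unknown BSE/T mode {mode!r}; expected one of {BSET_MODES}")
    impacts = list(impacts)
    if not impacts:
        raise UndefinedIndexError("BSE/T is undefined for an empty impact set")
    for ev in impacts:
        if ev.magnitude is None:
            raise ValueError("every impact needs a magnitude category assigned")
    n = len(impacts)
    if mode == "per_impact":
        total = 0.0
        for ev in impacts:
            if ev.interval_cat is None:
                raise ValueError("every impact needs an interval category assigned")
            total += ev.magnitude.severity_weight * ev.interval_cat.weight
        return total / n
    # category-mean mode: five terms, one per magnitude category
    total = 0.0
    for cat in MagnitudeCategory:
        group = [ev for ev in impacts if ev.magnitude == cat]
        if not group:
            continue
        if any(ev.interval_min is None for ev in group):
            raise ValueError("category-mean mode needs interval_min on every impact")
        mean_interval = sum(ev.interval_min for ev in group) / len(group)
        weight = categorize_interval(mean_interval).weight
        total += len(group) * cat.severity_weight * weight
    return total / n


@dataclass
class ExposureRecord:
    """Per position-game exposure summary."""

    game_id: str
    position: PlayerPosition
    n_impacts: int
    freq_by_magnitude: dict  # MagnitudeCategory -> count
    mean_interval_min: Optional[float]
    bset: Optional[float]  # None when n_impacts == 0 (undefined)
    mode: str = "per_impact"
    suspected: int = 0
    pile_ups: int = 0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.freq_by_magnitude.values()) != self.n_impacts:
            raise ValueError("freq_by_magnitude must sum to n_impacts")
        if self.bset is not None and not 1.0 - 1e-9 <= self.bset <= 20.0 + 1e-9:
            raise ValueError(f"BSE/T out of attainable range [1, 20]: {self.bset}")


def game_exposure(
    log: GameLog,
    position: PlayerPosition,
    table: Optional[ExemplarTable] = None,
    meta: Optional[GameMeta] = None,
    timeline: GameTimeline = DEFAULT_TIMELINE,
    mode: str = "per_impact",
    first_impact: str = "kickoff",
) -> ExposureRecord:
    """Run the full per-game scoring pipeline for one position.

    Selects the position's confirmed primary-type impacts, assigns exemplar
    strain magnitudes, computes real inter-impact intervals (between that
    position's consecutive impacts), and scores BSE/T.  With
    ``first_impact='exclude'`` the game's first impact carries no interval
    and is left out of the BSE/T computation (it still counts toward
    ``n_impacts`` and the magnitude frequencies).
    """
    position = PlayerPosition(position)
    table = table if table is not None else bundled_default_table()
    meta = meta if meta is not None else log.meta
    own = [ev for ev in log if ev.position == position]
    suspected = sum(1 for ev in own if ev.status is ImpactStatus.SUSPECTED)
    pile_ups = sum(1 for ev in own if ev.status is ImpactStatus.MULTIPLE)
    analysis = select_analysis_set(own)
    freq = Counter()
    for ev in analysis:
        try:
            assign_mps(ev, table)
        except Exception as exc:
            raise RuntimeError(f"strain assignment stage failed: {exc}") from exc
        freq[ev.magnitude] += 1
    if analysis:
        try:
            gaps = real_intervals(analysis, meta, timeline, first_impact=first_impact)
        except Exception as exc:
            raise RuntimeError(f"interval stage failed: {exc}") from exc
        finite = gaps[np.isfinite(gaps)]
        mean_interval = float(np.mean(finite)) if finite.size else None
        scorable = [ev for ev in analysis if ev.interval_cat is not None]
        bset = compute_bset(scorable, mode=mode) if scorable else None
    else:
        mean_interval = None
        bset = None
    return ExposureRecord(
        game_id=log.game_id or "",
        position=position,
        n_impacts=len(analysis),
        freq_by_magnitude={cat: freq.get(cat, 0) for cat in MagnitudeCategory},
        mean_interval_min=mean_interval,
        bset=bset,
        mode=mode,
        suspected=suspected,
        pile_ups=pile_ups,
    )


def records_frame(records: Sequence[ExposureRecord]) -> pd.DataFrame:
    """Flatten exposure records into a tabular (CSV-ready) DataFrame."""
    rows = []
    for r in records:
        row = {
            "game_id": r.game_id,
            "position": r.position.value,
            "n_impacts": r.n_impacts,
            "mean_interval_min": r.mean_interval_min,
            "bset": r.bset,
            "mode": r.mode,
            "suspected": r.suspected,
            "pile_ups": r.pile_ups,
        }
        for cat in MagnitudeCategory:
            row[f"n_{cat.name.lower()}"] = r.freq_by_magnitude.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def season_aggregate(
    records: Sequence[ExposureRecord], games_per_season: int = 16
) -> pd.DataFrame:
    """Per-position season summary of frequency and BSE/T.

    Per-game mean and SD of confirmed-primary frequency and of BSE/T
    (defined games only), plus the per-season frequency estimate (per-game
    mean x ``games_per_season``).
    """
    by_pos: dict = {}
    for r in records:
        by_pos.setdefault(r.position, []).append(r)
    rows = []
    for pos in PlayerPosition:
        recs = by_pos.get(pos)
        if not recs:
            continue
        counts = np.array([r.n_impacts for r in recs], dtype=float)
        bsets = np.array([r.bset for r in recs if r.bset is not None], dtype=float)
        ddof = 1 if len(counts) > 1 else 0
        rows.append(
            {
                "position": pos.value,
                "games": len(recs),
                "per_game_mean": float(np.mean(counts)),
                "per_game_sd": float(np.std(counts, ddof=ddof)),
                "per_season": float(np.mean(counts)) * games_per_season,
                "bset_mean": float(np.mean(bsets)) if bsets.size else math.nan,
                "bset_sd": float(np.std(bsets, ddof=1 if bsets.size > 1 else 0)) if bsets.size else math.nan,
                "mean_interval_min": float(
                    np.mean([r.mean_interval_min for r in recs if r.mean_interval_min is not None])
                )
                if any(r.mean_interval_min is not None for r in recs)
                else math.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("position")
    df.attrs["grand_mean_per_season"] = float(df["per_season"].mean()) if len(df) else math.nan
    return df


# ---------------------------------------------------------------------------
# exposure profiles

#: Default profile membership: profile 1 = few impacts of high magnitude at
#: long intervals; profile 2 = mid-range frequency, all magnitudes; profile
#: 3 = highest frequency, predominantly low magnitude, shortest intervals.
DEFAULT_PROFILE_MEMBERSHIP = {
    PlayerPosition.QB: (1,),
    PlayerPosition.WR: (1,),
    PlayerPosition.DB: (1,),
    PlayerPosition.LB: (2,),
    PlayerPosition.RB: (2,),
    PlayerPosition.OL: (3,),
    PlayerPosition.DL: (3,),
    PlayerPosition.TE: (2, 3),  # overlaps both lineman and receiver roles
}

#: Positions whose exposure straddles two profiles under the default map.
OVERLAPPING_POSITIONS = frozenset(
    p for p, profiles in DEFAULT_PROFILE_MEMBERSHIP.items() if len(profiles) > 1
)


@dataclass
class ProfileSummary:
    """Descriptive contrast for one exposure profile (no clustering is done)."""

    profile_id: int
    positions: list
    overlapping: list
    mean_frequency: float
    mean_bset: float
    mean_interval_min: float
    magnitude_mix: dict  # MagnitudeCategory -> share of impacts


def profile_report(
    summaries: pd.DataFrame,
    records: Optional[Sequence[ExposureRecord]] = None,
    membership: Optional[dict] = None,
) -> list:
    """Group per-position summaries into exposure profiles.

    ``summaries`` is the output of :func:`season_aggregate` (needs >= 2
    positions).  The magnitude mix per profile is computed from ``records``
    when given, else left empty.  Membership defaults to the published
    three-profile structure and may be overridden with a
    ``{position: (profile ids...)}`` map.
    """
    if len(summaries) < 2:
        raise ValueError("profile_report needs summaries for at least 2 positions")
    membership = membership if membership is not None else DEFAULT_PROFILE_MEMBERSHIP
    membership = {PlayerPosition(p): tuple(v) if isinstance(v, (tuple, list)) else (v,) for p, v in membership.items()}
    for pos_code in summaries.index:
        if PlayerPosition(pos_code) not in membership:
            raise ValueError(f"position {pos_code} absent from profile membership map")
    profile_ids = sorted({pid for pids in membership.values() for pid in pids})
    out = []
    for pid in profile_ids:
        members = [p for p in membership if pid in membership[p] and p.value in summaries.index]
        if not members:
            continue
        sub = summaries.loc[[p.value for p in members]]
        mix: dict = {}
        if records is not None:
            counts = Counter()
            for r in records:
                if r.position in members:
                    counts.update(r.freq_by_magnitude)
            total = sum(counts.values())
            if total:
                mix = {cat: counts.get(cat, 0) / total for cat in MagnitudeCategory}
        out.append(
            ProfileSummary(
                profile_id=pid,
                positions=[p.value for p in members],
                overlapping=[p.value for p in members if len(membership[p]) > 1],
                mean_frequency=float(sub["per_game_mean"].mean()),
                mean_bset=float(sub["bset_mean"].mean()),
                mean_interval_min=float(sub["mean_interval_min"].mean()),
                magnitude_mix=mix,
            )
        )
    return out
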