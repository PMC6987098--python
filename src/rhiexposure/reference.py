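"""Bundled study reference constants for professional American-style football.

These are the published per-position summaries from the 32-game film review
of 2009-2015 regular-season professional games that this package's scoring
scheme was developed on.  They serve three purposes: defaults for the
synthetic generator, inputs for career projections, and consistency anchors
for the reporting pipeline.  They are *inputs*, not computed results.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .impact_log import PlayerPosition, career_projection

__all__ = [
    "N_REFERENCE_GAMES",
    "GAMES_PER_SEASON",
    "PositionFrequencyReference",
    "FREQUENCY_REFERENCE",
    "EXEMPLAR_COUNTS",
    "TRIALS_PER_EXEMPLAR",
    "reference_frequency_table",
    "grand_mean_per_season",
]

#: Number of regular-season games reviewed in the reference study.
N_REFERENCE_GAMES = 32

#: Regular-season games per team per season (practices excluded).
GAMES_PER_SEASON = 16


@dataclass(frozen=True)
class PositionFrequencyReference:
    """One position's published frequency summary.

    ``total_confirmed``/``suspected``/``pile_ups`` are counts over the 32
    reviewed games; ``per_game_sd`` is the published per-game SD;
    ``avg_career_years`` is the average professional career length for the
    position and ``record_games`` the greatest number of games played on
    record, both used for career projections.
    """

    position: PlayerPosition
    total_confirmed: int
    per_game_sd: float
    suspected: int
    pile_ups: int
    avg_career_years: float
    record_games: int


FREQUENCY_REFERENCE = {
    PlayerPosition.QB: PositionFrequencyReference(PlayerPosition.QB, 73, 2.0, 23, 7, 3.08, 302),
    PlayerPosition.RB: PositionFrequencyReference(PlayerPosition.RB, 468, 5.4, 186, 10, 2.42, 226),
    PlayerPosition.WR: PositionFrequencyReference(PlayerPosition.WR, 106, 2.9, 33, 7, 2.21, 303),
    PlayerPosition.TE: PositionFrequencyReference(PlayerPosition.TE, 459, 6.1, 34, 10, 2.67, 270),
    PlayerPosition.OL: PositionFrequencyReference(PlayerPosition.OL, 637, 8.3, 31, 15, 3.67, 296),
    PlayerPosition.DL: PositionFrequencyReference(PlayerPosition.DL, 706, 8.5, 71, 5, 3.0, 282),
    PlayerPosition.LB: PositionFrequencyReference(PlayerPosition.LB, 377, 4.6, 82, 2, 3.0, 278),
    PlayerPosition.DB: PositionFrequencyReference(PlayerPosition.DB, 115, 2.5, 38, 10, 3.17, 295),
}

#: Laboratory exemplar reconstruction counts per position and event type.
EXEMPLAR_COUNTS = {
    PlayerPosition.QB: {"helmet": 5, "shoulder": 1, "hip_thigh": 0, "ground": 10},
    PlayerPosition.RB: {"helmet": 14, "shoulder": 13, "hip_thigh": 6, "ground": 16},
    PlayerPosition.WR: {"helmet": 9, "shoulder": 2, "hip_thigh": 3, "ground": 14},
    PlayerPosition.TE: {"helmet": 11, "shoulder": 11, "hip_thigh": 3, "ground": 12},
    PlayerPosition.OL: {"helmet": 7, "shoulder": 8, "hip_thigh": 3, "ground": 5},
    PlayerPosition.DL: {"helmet": 11, "shoulder": 9, "hip_thigh": 3, "ground": 8},
    PlayerPosition.LB: {"helmet": 10, "shoulder": 9, "hip_thigh": 3, "ground": 10},
    PlayerPosition.DB: {"helmet": 5, "shoulder": 9, "hip_thigh": 4, "ground": 15},
}

#: Each exemplar condition was physically reconstructed in triplicate.
TRIALS_PER_EXEMPLAR = 3


def reference_frequency_table(games_per_season: int = GAMES_PER_SEASON) -> pd.DataFrame:
    """Recompute the published frequency table from its raw count inputs.

    For each position: per-game mean (total / 32, 1 decimal), per-season
    estimate (unrounded mean x 16, 1 decimal), and the two career
    projections (average-career and record-games extrapolations).
    """
    rows = []
    for pos, ref in FREQUENCY_REFERENCE.items():
        mean = ref.total_confirmed / N_REFERENCE_GAMES
        per_game_mean = round(mean, 1)
        per_season = round(mean * games_per_season, 1)
        est_avg, est_record = career_projection(
            per_game_mean, per_season, ref.avg_career_years, ref.record_games
        )
        rows.append(
            {
                "position": pos.value,
                "total_confirmed": ref.total_confirmed,
                "per_game_mean": per_game_mean,
                "per_game_sd": ref.per_game_sd,
                "per_season": per_season,
                "suspected": ref.suspected,
                "pile_ups": ref.pile_ups,
                "avg_career_years": ref.avg_career_years,
                "career_avg_estimate": est_avg,
                "record_games": ref.record_games,
                "career_record_estimate": est_record,
            }
        )
    return pd.DataFrame(rows).set_index("position")


def grand_mean_per_season(games_per_season: int = GAMES_PER_SEASON) -> float:
    """Mean of the eight per-position per-season estimates (impacts/season)."""
    table = reference_frequency_table(games_per_season)
    return float(table["per_season"].mean())
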