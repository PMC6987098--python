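"""BSE/T index computation, bounds, and aggregation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from rhiexposure import (
    EventKind,
    GameLog,
    GameMeta,
    IntervalCategory,
    MagnitudeCategory,
    PlayerPosition,
    compute_bset,
    game_exposure,
    profile_report,
    season_aggregate,
)
from rhiexposure.exposure import (
    DEFAULT_PROFILE_MEMBERSHIP,
    ExposureRecord,
    UndefinedIndexError,
    records_frame,
)
from rhiexposure.reference import reference_frequency_table

from conftest import make_impact


def scored_impact(magnitude, interval_cat, interval_min=None):
    ev = make_impact(event=EventKind.HELMET)
    ev.magnitude = magnitude
    ev.interval_cat = interval_cat
    ev.interval_min = (
        interval_min if interval_min is not None else sum(interval_cat.bounds_min[:1]) + 1.0
    )
    return ev


class TestComputeBset:
    def test_two_moderate_impacts_at_short_intervals(self):
        impacts = [
            scored_impact(MagnitudeCategory.MODERATE, IntervalCategory.VERY_LOW, 5.0)
            for _ in range(2)
        ]
        # (2 impacts * severity 3 * weight 4) / 2 in both modes
        assert compute_bset(impacts, "per_impact") == 12.0
        assert compute_bset(impacts, "category_mean") == 12.0

    def test_floor_is_one(self):
        impacts = [scored_impact(MagnitudeCategory.VERY_LOW, IntervalCategory.HIGH, 100.0)]
        assert compute_bset(impacts) == 1.0

    def test_ceiling_is_twenty_regardless_of_n(self):
        for n in (1, 4, 9):
            impacts = [
                scored_impact(MagnitudeCategory.VERY_HIGH, IntervalCategory.VERY_LOW, 2.0)
                for _ in range(n)
            ]
            assert compute_bset(impacts) == 20.0

    def test_empty_is_undefined_not_zero(self):
        with pytest.raises(UndefinedIndexError):
            compute_bset([])

    def test_modes_agree_on_homogeneous_interval_categories(self):
        impacts = [
            scored_impact(MagnitudeCategory.LOW, IntervalCategory.LOW, 20.0),
            scored_impact(MagnitudeCategory.LOW, IntervalCategory.LOW, 25.0),
            scored_impact(MagnitudeCategory.HIGH, IntervalCategory.VERY_LOW, 3.0),
        ]
        assert compute_bset(impacts, "per_impact") == pytest.approx(
            compute_bset(impacts, "category_mean")
        )

    def test_modes_can_differ_on_mixed_intervals(self):
        # low-magnitude impacts straddling an interval-category boundary:
        # per-impact weights each one, category-mean weights their mean
        impacts = [
            scored_impact(MagnitudeCategory.LOW, IntervalCategory.VERY_LOW, 1.0),
            scored_impact(MagnitudeCategory.LOW, IntervalCategory.HIGH, 120.0),
        ]
        per_impact = compute_bset(impacts, "per_impact")  # (2*4 + 2*1)/2 = 5
        cat_mean = compute_bset(impacts, "category_mean")  # mean 60.5 -> moderate, (2*2*2)/2 = 4
        assert per_impact == 5.0 and cat_mean == 4.0

    @given(
        st.lists(
            st.tuples(st.sampled_from(list(MagnitudeCategory)),
                      st.sampled_from(list(IntervalCategory))),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_order_invariant(self, pairs):
        impacts = [scored_impact(m, i) for m, i in pairs]
        value = compute_bset(impacts)
        assert 1.0 <= value <= 20.0
        assert compute_bset(list(reversed(impacts))) == pytest.approx(value)

    def test_mean_property(self):
        impacts = [scored_impact(MagnitudeCategory.MODERATE, IntervalCategory.LOW, 20.0)] * 3
        base = compute_bset(impacts)  # 9.0
        extra = scored_impact(MagnitudeCategory.MODERATE, IntervalCategory.LOW, 20.0)
        assert compute_bset(impacts + [extra]) == pytest.approx(base)


class TestGameExposure:
    def test_hand_traced_fixture(self, traced_game):
        record = game_exposure(traced_game, PlayerPosition.OL)
        assert record.n_impacts == 3  # 'other' and suspected excluded
        assert record.suspected == 1
        assert record.freq_by_magnitude[MagnitudeCategory.MODERATE] == 1
        assert record.freq_by_magnitude[MagnitudeCategory.LOW] == 2
        # intervals 15, 18, 17 real minutes -> all 'low' (weight 3)
        assert record.mean_interval_min == pytest.approx((15 + 18 + 17) / 3)
        assert record.bset == pytest.approx(7.0)

    def test_category_mean_mode_matches_trace(self, traced_game):
        record = game_exposure(traced_game, PlayerPosition.OL, mode="category_mean")
        assert record.bset == pytest.approx(7.0)
        assert record.mode == "category_mean"

    def test_empty_analysis_set_gives_undefined_index(self, meta_factor3):
        log = GameLog(meta=meta_factor3, impacts=[])
        record = game_exposure(log, PlayerPosition.QB)
        assert record.n_impacts == 0 and record.bset is None

    def test_exclude_mode_drops_first_from_scoring(self, traced_game):
        record = game_exposure(traced_game, PlayerPosition.OL, first_impact="exclude")
        # remaining two impacts: helmet low*low(3)=6, shoulder low*low(3)=6
        assert record.bset == pytest.approx(6.0)
        assert record.n_impacts == 3  # frequency still counts all three

    def test_record_invariants(self, traced_game):
        record = game_exposure(traced_game, PlayerPosition.OL)
        assert sum(record.freq_by_magnitude.values()) == record.n_impacts
        assert 1.0 <= record.bset <= 20.0


class TestSeasonAggregate:
    def test_grand_mean_of_published_per_season_estimates(self):
        # the eight published per-season estimates average to ~184
        table = reference_frequency_table()
        grand = table["per_season"].mean()
        assert grand == pytest.approx(183.8, abs=0.05)
        assert round(grand) == 184

    def test_single_record_mean_is_value_sd_zero(self):
        rec = ExposureRecord(
            game_id="G1", position=PlayerPosition.QB, n_impacts=2,
            freq_by_magnitude={c: (2 if c is MagnitudeCategory.HIGH else 0) for c in MagnitudeCategory},
            mean_interval_min=20.0, bset=12.0,
        )
        table = season_aggregate([rec])
        row = table.loc["QB"]
        assert row["per_game_mean"] == 2.0 and row["per_game_sd"] == 0.0
        assert row["per_season"] == 32.0
        assert row["bset_mean"] == 12.0

    def test_records_frame_round_trip_columns(self, traced_game):
        record = game_exposure(traced_game, PlayerPosition.OL)
        df = records_frame([record])
        assert df.loc[0, "n_moderate"] == 1
        assert df.loc[0, "bset"] == pytest.approx(7.0)


class TestProfileReport:
    def _summaries(self):
        records = []
        freqs = {PlayerPosition.QB: 2, PlayerPosition.WR: 3, PlayerPosition.DB: 3,
                 PlayerPosition.LB: 11, PlayerPosition.RB: 14, PlayerPosition.TE: 14,
                 PlayerPosition.OL: 19, PlayerPosition.DL: 22}
        for pos, n in freqs.items():
            records.append(ExposureRecord(
                game_id="G1", position=pos, n_impacts=n,
                freq_by_magnitude={c: (n if c is MagnitudeCategory.LOW else 0) for c in MagnitudeCategory},
                mean_interval_min=100.0 / n, bset=8.0,
            ))
        return season_aggregate(records), records

    def test_default_membership_three_profiles_with_te_overlap(self):
        summaries, records = self._summaries()
        profiles = profile_report(summaries, records=records)
        assert [p.profile_id for p in profiles] == [1, 2, 3]
        p2, p3 = profiles[1], profiles[2]
        assert "TE" in p2.positions and "TE" in p3.positions
        assert p2.overlapping == ["TE"] and p3.overlapping == ["TE"]
        # profile 3 has the highest frequency and the shortest intervals
        assert profiles[2].mean_frequency > profiles[1].mean_frequency > profiles[0].mean_frequency
        assert profiles[2].mean_interval_min < profiles[0].mean_interval_min

    def test_override_single_profile(self):
        summaries, records = self._summaries()
        membership = {pos: (1,) for pos in DEFAULT_PROFILE_MEMBERSHIP}
        profiles = profile_report(summaries, records=records, membership=membership)
        assert len(profiles) == 1 and len(profiles[0].positions) == 8

    def test_missing_position_in_membership_rejected(self):
        summaries, records = self._summaries()
        membership = {PlayerPosition.QB: (1,)}
        with pytest.raises(ValueError, match="membership"):
            profile_report(summaries, membership=membership)
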