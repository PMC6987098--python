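import pytest

from rhiexposure import (
    ClockStamp,
    EventKind,
    GameLog,
    GameMeta,
    ImpactEvent,
    ImpactStatus,
    PlayerPosition,
)


def make_impact(
    position=PlayerPosition.OL,
    event=EventKind.HELMET,
    status=ImpactStatus.CONFIRMED,
    quarter=1,
    clock="10:00",
    head_location="front",
    elevation=3,
    game_id="G1",
    **kwargs,
):
    if status is ImpactStatus.CONFIRMED and head_location is None:
        head_location = "front"
    return ImpactEvent(
        game_id=game_id,
        position=position,
        player_ref=f"{PlayerPosition(position).value}1",
        event=event,
        status=status,
        stamp=ClockStamp.parse(quarter, clock),
        head_location=head_location,
        elevation_level=elevation if head_location not in (None, "crown") else None,
        **kwargs,
    )


@pytest.fixture
def meta_factor3():
    """Game metadata with a stop factor of exactly 3 (180 real min / 60 clock min)."""
    return GameMeta(game_id="G1", broadcast_duration_min=180.0, clock_duration_min=60.0)


@pytest.fixture
def traced_game(meta_factor3):
    """A hand-traceable one-position game.

    Three confirmed primary OL impacts (interval from kickoff, stop factor 3):

    ======  ========  ==============  ===========  ========  ============
    event   stamp     real interval   int. weight  MPS (%)   severity
    ======  ========  ==============  ===========  ========  ============
    ground  Q1 10:00  5*3 = 15        low -> 3     20.8      moderate, 3
    helmet  Q1 04:00  6*3 = 18        low -> 3     12.7      low, 2
    should. Q2 14:00  5*3 + 2 = 17    low -> 3     14.1      low, 2
    ======  ========  ==============  ===========  ========  ============

    BSE/T = (3*3 + 2*3 + 2*3) / 3 = 7.0 in both weighting modes.
    A confirmed 'other' impact and a suspected impact are present but must
    not enter the analysis set.
    """
    impacts = [
        make_impact(event=EventKind.GROUND, quarter=1, clock="10:00"),
        make_impact(event=EventKind.HELMET, quarter=1, clock="04:00"),
        make_impact(event=EventKind.SHOULDER, quarter=2, clock="14:00"),
        make_impact(event=EventKind.OTHER, quarter=3, clock="10:00", event_sublabel="back"),
        make_impact(event=EventKind.HELMET, status=ImpactStatus.SUSPECTED,
                    quarter=4, clock="05:00", head_location=None, elevation=None),
    ]
    return GameLog(meta=meta_factor3, impacts=impacts)
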