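"""Map impact conditions to brain-tissue maximum principal strain (MPS).

Every confirmed impact of a primary event type is assigned the MPS measured
for the laboratory exemplar reconstruction of its impact condition (event
type x velocity level x head location, per position).  The bundled default
table carries the published position-by-event-type mean strains; finer keyed
tables (down to the full condition) can be supplied by the user.  Assigned
strain is binned into five ordinal magnitude categories with severity
weights 1-5 used by the BSE/T exposure index.

Also exposes the linearly viscoelastic shear relaxation modulus
``G(t) = G_inf + (G0 - G_inf) * exp(-beta * t)`` with the bundled brain
tissue constants, for reference calculations.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .impact_log import EventKind, ImpactEvent, ImpactStatus, PlayerPosition, PRIMARY_EVENT_KINDS
from .kinematics import VelocityLevel

__all__ = [
    "MagnitudeCategory",
    "MPS_BOUNDS_PERCENT",
    "ExemplarKey",
    "ExemplarEntry",
    "ExemplarTable",
    "UnmappedConditionError",
    "bundled_default_table",
    "read_exemplar_table",
    "write_exemplar_table",
    "assign_mps",
    "categorize_mps",
    "exemplar_velocity",
    "TissueMaterial",
    "BRAIN_MATERIALS",
    "shear_modulus",
]


class MagnitudeCategory(enum.IntEnum):
    """Ordinal MPS magnitude category; the integer value is the severity weight."""

    VERY_LOW = 1
    LOW = 2
    MODERATE = 3
    HIGH = 4
    VERY_HIGH = 5

    @property
    def severity_weight(self) -> int:
        return int(self)

    @property
    def bounds_percent(self) -> tuple:
        edges = (0.0,) + MPS_BOUNDS_PERCENT + (100.0,)
        return edges[self - 1], edges[self]

    @property
    def risk_note(self) -> str:
        """Descriptive injury-risk annotation; never used in computation."""
        return _RISK_NOTES[self]


#: Interior bounds (% MPS) of the five magnitude categories; half-open on
#: the left of each upper bound: [0,8), [8,17), [17,26), [26,35), [35,100].
MPS_BOUNDS_PERCENT = (8.0, 17.0, 26.0, 35.0)

_RISK_NOTES = {
    MagnitudeCategory.VERY_LOW: "below functional-impairment strain thresholds",
    MagnitudeCategory.LOW: "sub-concussive; associated with cumulative structural change",
    MagnitudeCategory.MODERATE: "approximately 50% risk of concussion injury",
    MagnitudeCategory.HIGH: "average estimates for sustaining concussive injury",
    MagnitudeCategory.VERY_HIGH: "approximately 50% risk of loss of consciousness / persistent symptoms",
}


def categorize_mps(mps_percent: float) -> MagnitudeCategory:
    """Bin a strain percentage into its ordinal magnitude category."""
    if not 0.0 <= mps_percent <= 100.0:
        raise ValueError(f"mps_percent out of [0, 100]: {mps_percent}")
    return MagnitudeCategory(bisect_right(MPS_BOUNDS_PERCENT, mps_percent) + 1)


# ---------------------------------------------------------------------------
# exemplar tables

class UnmappedConditionError(KeyError):
    """No exemplar entry matches the impact condition at any fallback level."""


@dataclass(frozen=True)
class ExemplarKey:
    """An impact condition: (position) x event x (velocity level) x (location)."""

    event: EventKind
    position: Optional[PlayerPosition] = None
    velocity_level: Optional[VelocityLevel] = None
    head_location: Optional[str] = None

    def __post_init__(self):
        if self.event not in PRIMARY_EVENT_KINDS:
            raise ValueError(f"exemplar keys cover primary event kinds only, got {self.event}")


@dataclass(frozen=True)
class ExemplarEntry:
    mps_percent: float
    provenance: str = ""

    def __post_init__(self):
        if not 0.0 <= self.mps_percent <= 100.0:
            raise ValueError(f"mps_percent out of [0, 100]: {self.mps_percent}")


@dataclass
class Assignment:
    """An MPS assignment plus how specific the matched key was."""

    mps_percent: float
    provenance: str
    fallback_level: str  # "exact" | "position_event" | "event_collapsed"


class ExemplarTable:
    """Exemplar strain lookup with a documented fallback chain.

    Lookup tries, in order: the exact condition key; the (position, event)
    mean; the position-collapsed event mean.  The fallback level used is
    recorded on the returned :class:`Assignment`.
    """

    def __init__(self, entries: Optional[dict] = None):
        self.entries: dict = dict(entries or {})

    def add(self, key: ExemplarKey, mps_percent: float, provenance: str = "") -> None:
        self.entries[key] = ExemplarEntry(mps_percent, provenance)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(
        self,
        event: EventKind,
        position: Optional[PlayerPosition] = None,
        velocity_level: Optional[VelocityLevel] = None,
        head_location: Optional[str] = None,
    ) -> Assignment:
        event = EventKind(event)
        chain = [
            ("exact", ExemplarKey(event, position, velocity_level, head_location)),
            ("position_event", ExemplarKey(event, position)),
            ("event_collapsed", ExemplarKey(event)),
        ]
        for level, key in chain:
            entry = self.entries.get(key)
            if entry is not None:
                prov = entry.provenance
                if level != "exact":
                    prov = f"{prov} [fallback: {level}]".strip()
                return Assignment(entry.mps_percent, prov, level)
        raise UnmappedConditionError(
            f"no exemplar entry for event={event.value}, position="
            f"{getattr(position, 'value', position)}, velocity_level={velocity_level}, "
            f"head_location={head_location} at any fallback level"
        )


#: Published mean MPS (%) from exemplar physical reconstructions, by field
#: position and event type.  ``None``: no exemplar existed for the cell.
#: The DB helmet cell is ambiguous in the published table (a mean/CI scale
#: mix); 24.2 is the plausible reading, marked provenance-suspect below and
#: freely overridable via a user table.
_TABLE_POSITION_EVENT_MPS = {
    PlayerPosition.QB: {"helmet": 24.1, "shoulder": 11.9, "hip_thigh": None, "ground": 27.4},
    PlayerPosition.RB: {"helmet": 25.3, "shoulder": 16.3, "hip_thigh": 10.4, "ground": 18.0},
    PlayerPosition.WR: {"helmet": 22.5, "shoulder": 14.1, "hip_thigh": 8.7, "ground": 25.2},
    PlayerPosition.TE: {"helmet": 19.5, "shoulder": 17.0, "hip_thigh": 11.5, "ground": 22.7},
    PlayerPosition.OL: {"helmet": 12.7, "shoulder": 14.1, "hip_thigh": 7.5, "ground": 20.8},
    PlayerPosition.DL: {"helmet": 19.7, "shoulder": 17.6, "hip_thigh": 9.6, "ground": 12.5},
    PlayerPosition.LB: {"helmet": 18.4, "shoulder": 18.3, "hip_thigh": 21.3, "ground": 17.3},
    PlayerPosition.DB: {"helmet": 24.2, "shoulder": 18.0, "hip_thigh": 14.9, "ground": 23.5},
}

#: Position-collapsed mean MPS (%) per position (all event types pooled).
COLLAPSED_POSITION_MPS = {
    PlayerPosition.QB: 25.4,
    PlayerPosition.RB: 17.1,
    PlayerPosition.WR: 21.8,
    PlayerPosition.TE: 19.1,
    PlayerPosition.OL: 14.3,
    PlayerPosition.DL: 16.3,
    PlayerPosition.LB: 18.3,
    PlayerPosition.DB: 21.1,
}

_SUSPECT_CELLS = {(PlayerPosition.DB, EventKind.HELMET)}


def bundled_default_table() -> ExemplarTable:
    """The bundled exemplar strain table (position x event-type means).

    Event-collapsed fallback entries are the unweighted means of the
    per-position cells for each event type, so conditions with no printed
    cell (e.g. QB hip/thigh) still resolve through the fallback chain.
    """
    table = ExemplarTable()
    by_event: dict = {}
    for pos, cells in _TABLE_POSITION_EVENT_MPS.items():
        for event_name, mps in cells.items():
            if mps is None:
                continue
            event = EventKind(event_name)
            prov = "bundled position-by-event reconstruction mean"
            if (pos, event) in _SUSPECT_CELLS:
                prov += " (provenance suspect: ambiguous printed cell; override if needed)"
            table.add(ExemplarKey(event, pos), mps, prov)
            by_event.setdefault(event, []).append(mps)
    for event, values in by_event.items():
        table.add(
            ExemplarKey(event),
            sum(values) / len(values),
            "bundled event mean collapsed over positions",
        )
    return table


_CSV_COLUMNS = ["position", "event_type", "velocity_level", "head_location", "mps_percent", "provenance"]


def read_exemplar_table(source) -> ExemplarTable:
    """Read a user exemplar table from CSV (full condition keys supported)."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in ("event_type", "mps_percent") if c not in df.columns]
    if missing:
        raise ValueError(f"exemplar table missing column(s): {', '.join(missing)}")
    table = ExemplarTable()
    for row in df.to_dict("records"):
        pos = row.get("position", "").strip()
        vel = row.get("velocity_level", "").strip()
        loc = row.get("head_location", "").strip()
        velocity_level = None
        if vel:
            kind, _, level = vel.partition(":")
            from .kinematics import Level5, Mechanism

            velocity_level = VelocityLevel(Mechanism(kind), Level5[level.upper()])
        key = ExemplarKey(
            event=EventKind(row["event_type"].strip()),
            position=PlayerPosition(pos.upper()) if pos else None,
            velocity_level=velocity_level,
            head_location=loc or None,
        )
        table.add(key, float(row["mps_percent"]), row.get("provenance", ""))
    return table


def write_exemplar_table(table: ExemplarTable, path) -> None:
    rows = []
    for key, entry in table.entries.items():
        rows.append(
            {
                "position": key.position.value if key.position else "",
                "event_type": key.event.value,
                "velocity_level": str(key.velocity_level) if key.velocity_level else "",
                "head_location": key.head_location or "",
                "mps_percent": entry.mps_percent,
                "provenance": entry.provenance,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(Path(path), index=False)


def assign_mps(impact: ImpactEvent, table: ExemplarTable) -> float:
    """Assign the exemplar MPS for an impact's condition and record it.

    The impact must be confirmed and of a primary event type.  Sets
    ``impact.mps_percent`` and ``impact.magnitude`` and records the fallback
    level in the impact annotations.
    """
    if impact.status is not ImpactStatus.CONFIRMED:
        raise ValueError("MPS is only assigned to confirmed impacts")
    if impact.event not in PRIMARY_EVENT_KINDS:
        raise ValueError(
            f"MPS is only assigned to primary event kinds, got {impact.event}"
        )
    assignment = table.lookup(
        event=impact.event,
        position=impact.position,
        velocity_level=impact.velocity_level,
        head_location=impact.head_location,
    )
    impact.mps_percent = assignment.mps_percent
    impact.magnitude = categorize_mps(assignment.mps_percent)
    impact.annotations["mps_provenance"] = assignment.provenance
    impact.annotations["mps_fallback_level"] = assignment.fallback_level
    return assignment.mps_percent


def exemplar_velocity(velocities_mps: Sequence[float], level: VelocityLevel) -> float:
    """Reconstruction speed for the exemplar representing a condition.

    A single observed impact uses its own speed; two or three use their
    arithmetic mean; four or more use the midrange of the velocity level's
    nominal bounds (e.g. low collision = 3.25 m/s).  The open-ended top
    level has no midrange, so the mean is used there for any count.
    """
    values = list(velocities_mps)
    if not values:
        raise ValueError("exemplar_velocity requires at least one observed velocity")
    if len(values) <= 3:
        return sum(values) / len(values)
    lo, hi = level.bounds_mps
    if math.isinf(hi):
        return sum(values) / len(values)
    return level.midrange_mps


# ---------------------------------------------------------------------------
# viscoelastic shear relaxation modulus

@dataclass(frozen=True)
class TissueMaterial:
    """Viscoelastic shear parameters of a brain tissue component.

    ``g0_kpa``/``g_inf_kpa`` are the short- and long-term shear moduli,
    ``beta_per_s`` the exponential decay constant, ``bulk_modulus_gpa`` the
    (nearly incompressible) bulk modulus.
    """

    name: str
    g0_kpa: float
    g_inf_kpa: float
    beta_per_s: float
    bulk_modulus_gpa: float

    def __post_init__(self):
        if not self.g0_kpa >= self.g_inf_kpa > 0:
            raise ValueError("require G0 >= G_inf > 0")
        if self.beta_per_s <= 0:
            raise ValueError("beta must be positive")


BRAIN_MATERIALS = {
    "cerebellum": TissueMaterial("cerebellum", 10.0, 2.0, 80.0, 2.19),
    "brain_stem": TissueMaterial("brain_stem", 22.5, 4.5, 80.0, 2.19),
    "white_matter": TissueMaterial("white_matter", 12.5, 2.5, 80.0, 2.19),
    "grey_matter": TissueMaterial("grey_matter", 10.0, 2.0, 80.0, 2.19),
}


def shear_modulus(t_s: float, material: TissueMaterial) -> float:
    """Shear relaxation modulus G(t) = G_inf + (G0 - G_inf) e^{-beta t}, in kPa."""
    if t_s < 0:
        raise ValueError(f"time must be non-negative, got {t_s}")
    return material.g_inf_kpa + (material.g0_kpa - material.g_inf_kpa) * math.exp(
        -material.beta_per_s * t_s
    )
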