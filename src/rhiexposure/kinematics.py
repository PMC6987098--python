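"""Impact velocity estimation from video frame tracks, and head-location coding.

Impact speed is estimated from broadcast footage: pixel coordinates of the
player's head in the 3-5 frames before contact are mapped onto the field
plane through a planar projective transform (homography) fitted to known
field-line correspondences, and speed is displacement over elapsed time.
Falls need a two-step resultant: horizontal motion is corrected for camera
panning by subtracting a static scene marker's apparent motion, and vertical
speed comes from the measured head-to-ground distances (scaled by the known
helmet width or length).

Velocity is then binned into five ordinal levels with separate bound tables
for collisions (helmet/shoulder/hip-thigh) and falls (ground), and the
struck location on the helmet is coded as one of six regions (front, front
boss, side, rear boss, rear, crown) from the impact azimuth, collapsing left
and right.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Mechanism",
    "Level5",
    "VelocityLevel",
    "HeadRegion",
    "HeadLocationCode",
    "FieldCalibration",
    "FrameTrack",
    "CalibrationError",
    "InsufficientDataError",
    "COLLISION_BOUNDS_MPS",
    "FALL_BOUNDS_MPS",
    "fit_homography",
    "collision_velocity",
    "fall_velocity",
    "fall_vertical_ballistic",
    "categorize_velocity",
    "mechanism_for_event",
    "assign_head_location",
]


class CalibrationError(ValueError):
    """Degenerate point configuration; no valid field calibration exists."""


class InsufficientDataError(ValueError):
    """Too few frame samples to estimate a velocity."""


class Mechanism(str, enum.Enum):
    """Impact mechanism governing which velocity bound table applies."""

    COLLISION = "collision"
    FALL = "fall"


class Level5(enum.IntEnum):
    """Five-step ordinal scale shared by velocity and strain categories."""

    VERY_LOW = 1
    LOW = 2
    MODERATE = 3
    HIGH = 4
    VERY_HIGH = 5


#: Interior bounds (m/s) of the five collision velocity levels; each level is
#: half-open, closed on the left: [0,2), [2,4.5), [4.5,7), [7,9.5), [9.5,inf).
COLLISION_BOUNDS_MPS = (2.0, 4.5, 7.0, 9.5)
#: Fall levels: [0,2), [2,4), [4,6), [6,8), [8,inf).
FALL_BOUNDS_MPS = (2.0, 4.0, 6.0, 8.0)

_BOUNDS = {Mechanism.COLLISION: COLLISION_BOUNDS_MPS, Mechanism.FALL: FALL_BOUNDS_MPS}


@dataclass(frozen=True)
class VelocityLevel:
    """An ordinal velocity level for a given mechanism."""

    kind: Mechanism
    level: Level5

    @property
    def bounds_mps(self) -> tuple:
        """(lower, upper) nominal bounds in m/s; upper is ``inf`` at the top."""
        edges = (0.0,) + _BOUNDS[self.kind] + (math.inf,)
        i = int(self.level) - 1
        return edges[i], edges[i + 1]

    @property
    def midrange_mps(self) -> float:
        """Midpoint of the level's nominal bounds (e.g. low collision = 3.25)."""
        lo, hi = self.bounds_mps
        if math.isinf(hi):
            raise ValueError(f"{self.level.name} has no upper bound; midrange undefined")
        return (lo + hi) / 2.0

    def __str__(self) -> str:
        return f"{self.kind.value}:{self.level.name.lower()}"


def mechanism_for_event(event) -> Mechanism:
    """Ground impacts are falls; helmet/shoulder/hip-thigh are collisions."""
    value = getattr(event, "value", event)
    return Mechanism.FALL if value == "ground" else Mechanism.COLLISION


def categorize_velocity(speed_mps: float, kind: Mechanism) -> VelocityLevel:
    """Bin a speed into its ordinal level for the given mechanism.

    Levels are half-open intervals closed on the left, so e.g. 4.5 m/s is a
    *moderate* collision and 2.0 m/s is *low* for either mechanism.
    """
    if speed_mps < 0:
        raise ValueError(f"speed must be non-negative, got {speed_mps}")
    kind = Mechanism(kind)
    idx = bisect_right(_BOUNDS[kind], speed_mps)
    return VelocityLevel(kind, Level5(idx + 1))


# ---------------------------------------------------------------------------
# field calibration (planar homography)

@dataclass
class FieldCalibration:
    """Planar projective mapping from image pixels to field meters."""

    matrix: np.ndarray  # 3x3, maps homogeneous pixel coords -> field coords
    residuals_m: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def rms_residual_m(self) -> float:
        if self.residuals_m.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.residuals_m**2)))

    def pixel_to_field(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) pixel points to (n, 2) field points in meters."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        homog = np.column_stack([pts, np.ones(len(pts))])
        mapped = homog @ self.matrix.T
        w = mapped[:, 2]
        if np.any(np.abs(w) < 1e-12):
            raise CalibrationError("point maps to infinity under calibration")
        return mapped[:, :2] / w[:, None]


def fit_homography(pixel_pts: Sequence, field_pts: Sequence) -> FieldCalibration:
    """Fit the pixel-to-field homography by the direct linear transform.

    Requires at least 4 non-collinear correspondences; with more than 4 the
    solution is least-squares (smallest singular vector of the stacked DLT
    system) and per-point reprojection residuals are reported.
    """
    px = np.asarray(pixel_pts, dtype=float)
    fp = np.asarray(field_pts, dtype=float)
    if px.shape != fp.shape or px.ndim != 2 or px.shape[1] != 2:
        raise ValueError("pixel_pts and field_pts must both be (n, 2) arrays")
    n = len(px)
    if n < 4:
        raise CalibrationError(f"need >= 4 correspondences, got {n}")

    def _normalize(pts):
        c = pts.mean(axis=0)
        scale = math.sqrt(2) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
        T = np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1.0]])
        return (np.column_stack([pts, np.ones(len(pts))]) @ T.T)[:, :2], T

    pxn, Tp = _normalize(px)
    fpn, Tf = _normalize(fp)
    rows = []
    for (x, y), (u, v) in zip(pxn, fpn):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A)
    # a second near-zero singular value means the solution is not unique
    # (all points collinear or otherwise degenerate)
    if s[-2] <= 1e-8 * s[0]:
        raise CalibrationError("degenerate (collinear) correspondence configuration")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tf) @ Hn @ Tp
    if abs(H[2, 2]) < 1e-12:
        raise CalibrationError("degenerate homography (vanishing scale)")
    H = H / H[2, 2]
    calib = FieldCalibration(matrix=H)
    mapped = calib.pixel_to_field(px)
    calib.residuals_m = np.linalg.norm(mapped - fp, axis=1)
    return calib


# ---------------------------------------------------------------------------
# frame tracks & velocities

@dataclass
class FrameTrack:
    """Ordered pixel samples of one tracked point (head, marker, or surface).

    ``helmet_scale_m_per_px`` optionally converts pixel displacements to
    meters using the known helmet width/length; when absent, coordinates are
    taken to be in meters already (e.g. after homography mapping).
    """

    fps: float
    frames: Sequence[int]
    points: np.ndarray  # (n, 2)
    helmet_scale_m_per_px: Optional[float] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.frames = list(self.frames)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.frames) != len(self.points):
            raise ValueError("frames and points length mismatch")
        if len(self.frames) < 2:
            raise InsufficientDataError("a frame track needs >= 2 samples")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def elapsed_s(self) -> float:
        return (self.frames[-1] - self.frames[0]) / self.fps


def collision_velocity(track: FrameTrack, calibration: FieldCalibration) -> float:
    """Pre-impact closing speed (m/s) of the head in the field plane.

    Maps the first and last of the 3-5 pre-impact samples to field
    coordinates and divides the straight-line displacement by elapsed time.
    """
    if len(track) < 3:
        raise InsufficientDataError(
            f"collision velocity needs 3-5 pre-impact samples, got {len(track)}"
        )
    pts = calibration.pixel_to_field(track.points)
    displacement = float(np.linalg.norm(pts[-1] - pts[0]))
    return displacement / track.elapsed_s


def fall_velocity(
    head_track: FrameTrack,
    marker_track: FrameTrack,
    vertical_distances_m: Sequence[float],
    mode: str = "finite_difference",
) -> float:
    """Resultant pre-impact fall speed (m/s) via the two-step procedure.

    Horizontal: per-frame head displacement minus the static scene marker's
    apparent displacement (removing camera panning), converted to meters by
    the helmet scale, averaged over frame pairs.  Vertical: the rate of
    change of the measured head-to-ground distances (``finite_difference``
    default) or a free-fall estimate from the initial drop height
    (``ballistic``).  The resultant is the Euclidean combination.
    """
    if head_track.frames != marker_track.frames:
        raise ValueError("head and marker tracks must share identical frame indices")
    if len(vertical_distances_m) < 2 and mode == "finite_difference":
        raise InsufficientDataError("need >= 2 vertical distances for finite differencing")
    scale = head_track.helmet_scale_m_per_px or 1.0
    dt = 1.0 / head_track.fps
    speeds = []
    for i in range(len(head_track) - 1):
        step = head_track.frames[i + 1] - head_track.frames[i]
        dh = head_track.points[i + 1] - head_track.points[i]
        dm = marker_track.points[i + 1] - marker_track.points[i]
        speeds.append(np.linalg.norm(dh - dm) * scale / (step * dt))
    horizontal = float(np.mean(speeds))
    if mode == "finite_difference":
        d = np.asarray(vertical_distances_m, dtype=float)
        vertical = abs(d[0] - d[-1]) / ((len(d) - 1) * dt)
    elif mode == "ballistic":
        vertical = fall_vertical_ballistic(max(vertical_distances_m))
    else:
        raise ValueError(f"unknown vertical mode {mode!r}")
    return math.hypot(horizontal, vertical)


def fall_vertical_ballistic(drop_height_m: float, g: float = 9.81) -> float:
    """Free-fall vertical speed sqrt(2 g h) from a drop height in meters."""
    if drop_height_m < 0:
        raise ValueError("drop height must be non-negative")
    return math.sqrt(2.0 * g * drop_height_m)


# ---------------------------------------------------------------------------
# head location coding

class HeadRegion(str, enum.Enum):
    FRONT = "front"
    FRONT_BOSS = "front_boss"
    SIDE = "side"
    REAR_BOSS = "rear_boss"
    REAR = "rear"
    CROWN = "crown"


@dataclass(frozen=True)
class HeadLocationCode:
    """A struck helmet region plus elevation band (1-5; unset for crown)."""

    location: HeadRegion
    elevation: Optional[int] = None

    def __post_init__(self):
        if self.location is HeadRegion.CROWN:
            if self.elevation is not None:
                raise ValueError("crown impacts carry no elevation level")
        else:
            if self.elevation is None or not 1 <= self.elevation <= 5:
                raise ValueError(f"elevation must be 1-5, got {self.elevation}")


# sector centers in degrees, eyes-forward = 0, after left/right mirroring
_SECTOR_EDGES = (22.5, 67.5, 112.5, 157.5)
_SECTOR_REGIONS = (
    HeadRegion.FRONT,
    HeadRegion.FRONT_BOSS,
    HeadRegion.SIDE,
    HeadRegion.REAR_BOSS,
    HeadRegion.REAR,
)


def assign_head_location(
    azimuth_deg: float, elevation_level: Optional[int] = None, is_top: bool = False
) -> HeadLocationCode:
    """Code a struck helmet location from impact azimuth and elevation.

    The transverse plane is divided into eight 45-degree sectors centered on
    0, +/-45, +/-90, +/-135 and 180 degrees (eyes forward = 0; front covers
    [337.5, 22.5)); left and right are collapsed so only five azimuthal
    regions remain, and impacts at the top of the helmet are crown
    regardless of azimuth.  Sector boundaries are half-open with the
    boundary azimuth belonging to the more rearward sector (22.5 -> front
    boss).
    """
    if is_top:
        return HeadLocationCode(HeadRegion.CROWN, None)
    az = azimuth_deg % 360.0
    if az > 180.0:  # mirror left onto right
        az = 360.0 - az
    idx = bisect_right(_SECTOR_EDGES, az)
    return HeadLocationCode(_SECTOR_REGIONS[idx], elevation_level)
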