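"""Velocity estimation, velocity levels and head-location coding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhiexposure import (
    FrameTrack,
    HeadRegion,
    Level5,
    Mechanism,
    assign_head_location,
    categorize_velocity,
    collision_velocity,
    fall_velocity,
    fit_homography,
)
from rhiexposure.kinematics import (
    CalibrationError,
    InsufficientDataError,
    fall_vertical_ballistic,
    mechanism_for_event,
)

SQUARE_PX = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


class TestHomography:
    def test_identity(self):
        calib = fit_homography(SQUARE_PX, SQUARE_PX)
        assert np.allclose(calib.matrix, np.eye(3), atol=1e-9)
        assert calib.rms_residual_m < 1e-9

    def test_pure_scaling_doubles_distances(self):
        calib = fit_homography(SQUARE_PX, [(2 * x, 2 * y) for x, y in SQUARE_PX])
        a, b = calib.pixel_to_field([(0.25, 0.25), (0.75, 0.75)])
        assert np.linalg.norm(b - a) == pytest.approx(2 * math.hypot(0.5, 0.5))

    def test_overdetermined_residual_matches_normal_equations_oracle(self):
        # 6 correspondences under an affine map plus noise; for an affine
        # fit the least-squares residual is computable by brute-force
        # normal equations on [x, y, 1] -> (u, v)
        rng = np.random.default_rng(11)
        px = rng.uniform(0, 10, size=(6, 2))
        A = np.array([[1.2, 0.1], [-0.2, 0.9]])
        t = np.array([3.0, -1.0])
        fp = px @ A.T + t + rng.normal(0, 0.05, size=(6, 2))
        calib = fit_homography(px, fp)
        # oracle: independent affine least squares
        X = np.column_stack([px, np.ones(6)])
        coef, *_ = np.linalg.lstsq(X, fp, rcond=None)
        affine_resid = np.linalg.norm(X @ coef - fp, axis=1)
        # the 8-dof homography can only do at least as well as the 6-dof affine
        assert calib.residuals_m.shape == (6,)
        assert np.sqrt(np.mean(calib.residuals_m**2)) <= np.sqrt(np.mean(affine_resid**2)) + 1e-9
        assert np.all(calib.residuals_m < 0.2)

    def test_collinear_points_rejected(self):
        pts = [(i, 0.0) for i in range(5)]
        with pytest.raises(CalibrationError):
            fit_homography(pts, pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError, match=">= 4"):
            fit_homography(SQUARE_PX[:3], SQUARE_PX[:3])


def _identity_calib():
    return fit_homography(SQUARE_PX, SQUARE_PX)


class TestCollisionVelocity:
    def test_displacement_over_time(self):
        # 1.0 m over 0.2 s -> 5.0 m/s
        track = FrameTrack(fps=25.0, frames=[0, 2, 5], points=[(0, 0), (0.4, 0), (1.0, 0)])
        assert collision_velocity(track, _identity_calib()) == pytest.approx(5.0)

    def test_zero_displacement(self):
        track = FrameTrack(fps=30.0, frames=[0, 1, 2], points=[(1, 1)] * 3)
        assert collision_velocity(track, _identity_calib()) == 0.0

    def test_five_samples_at_25fps(self):
        # 0.26 m per frame at 25 fps -> 6.5 m/s
        pts = [(0.26 * i, 0.0) for i in range(5)]
        track = FrameTrack(fps=25.0, frames=list(range(5)), points=pts)
        assert collision_velocity(track, _identity_calib()) == pytest.approx(6.5)

    def test_insufficient_samples(self):
        track = FrameTrack(fps=25.0, frames=[0, 1], points=[(0, 0), (1, 0)])
        with pytest.raises(InsufficientDataError):
            collision_velocity(track, _identity_calib())

    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariant_and_scale_linear(self, dx, dy, scale):
        pts = np.array([(0.0, 0.0), (0.5, 0.2), (1.0, 0.4)])
        track = FrameTrack(fps=25.0, frames=[0, 1, 2], points=pts)
        v0 = collision_velocity(track, _identity_calib())
        shifted = FrameTrack(fps=25.0, frames=[0, 1, 2], points=pts + [dx, dy])
        assert collision_velocity(shifted, _identity_calib()) == pytest.approx(v0, rel=1e-6, abs=1e-9)
        scaled = FrameTrack(fps=25.0, frames=[0, 1, 2], points=pts * scale)
        assert collision_velocity(scaled, _identity_calib()) == pytest.approx(scale * v0, rel=1e-6)


class TestFallVelocity:
    def _tracks(self, head_pts, marker_pts, fps=30.0):
        frames = list(range(len(head_pts)))
        return (
            FrameTrack(fps=fps, frames=frames, points=head_pts),
            FrameTrack(fps=fps, frames=frames, points=marker_pts),
        )

    def test_three_four_five_triangle(self):
        # horizontal 3 m/s (static marker), vertical 4 m/s -> resultant 5
        fps = 10.0
        head = [(0.3 * i, 0.0) for i in range(3)]
        marker = [(0.0, 0.0)] * 3
        h, m = self._tracks(head, marker, fps)
        distances = [1.0, 0.6, 0.2]  # 0.4 m per 0.1 s -> 4 m/s
        assert fall_velocity(h, m, distances) == pytest.approx(5.0)

    def test_everything_static_is_zero(self):
        h, m = self._tracks([(0, 0)] * 3, [(5, 5)] * 3)
        assert fall_velocity(h, m, [1.0, 1.0, 1.0]) == 0.0

    def test_camera_panning_subtracted(self):
        # camera pans at 1.0 m/s, head apparent 3.5 m/s, no vertical -> 2.5
        fps = 10.0
        head = [(0.35 * i, 0.0) for i in range(3)]
        marker = [(0.10 * i, 0.0) for i in range(3)]
        h, m = self._tracks(head, marker, fps)
        assert fall_velocity(h, m, [0.8, 0.8, 0.8]) == pytest.approx(2.5)

    def test_helmet_scale_converts_pixels(self):
        fps = 10.0
        # 10 px/frame at 0.03 m/px = 3 m/s horizontal
        head = FrameTrack(fps=fps, frames=[0, 1, 2],
                          points=[(10 * i, 0) for i in range(3)],
                          helmet_scale_m_per_px=0.03)
        marker = FrameTrack(fps=fps, frames=[0, 1, 2], points=[(0, 0)] * 3)
        assert fall_velocity(head, marker, [1.0, 1.0]) == pytest.approx(3.0)

    def test_mismatched_frames_rejected(self):
        h = FrameTrack(fps=30, frames=[0, 1, 2], points=[(0, 0)] * 3)
        m = FrameTrack(fps=30, frames=[0, 2, 4], points=[(0, 0)] * 3)
        with pytest.raises(ValueError, match="frame indices"):
            fall_velocity(h, m, [1.0, 0.5])

    def test_ballistic_mode(self):
        assert fall_vertical_ballistic(1.0) == pytest.approx(math.sqrt(2 * 9.81))


class TestVelocityLevels:
    @pytest.mark.parametrize(
        "speed,kind,expected",
        [
            (0.0, Mechanism.COLLISION, Level5.VERY_LOW),
            (0.0, Mechanism.FALL, Level5.VERY_LOW),
            (1.99, Mechanism.COLLISION, Level5.VERY_LOW),
            (2.0, Mechanism.COLLISION, Level5.LOW),
            (4.49, Mechanism.COLLISION, Level5.LOW),
            (4.5, Mechanism.COLLISION, Level5.MODERATE),
            (5.0, Mechanism.COLLISION, Level5.MODERATE),
            (7.0, Mechanism.COLLISION, Level5.HIGH),
            (9.5, Mechanism.COLLISION, Level5.VERY_HIGH),
            (4.0, Mechanism.FALL, Level5.MODERATE),
            (4.5, Mechanism.FALL, Level5.MODERATE),
            (6.0, Mechanism.FALL, Level5.HIGH),
            (8.0, Mechanism.FALL, Level5.VERY_HIGH),
        ],
    )
    def test_boundary_table(self, speed, kind, expected):
        assert categorize_velocity(speed, kind).level == expected

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError):
            categorize_velocity(-0.1, Mechanism.COLLISION)

    @given(st.floats(0, 20), st.floats(0, 20),
           st.sampled_from([Mechanism.COLLISION, Mechanism.FALL]))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_speed(self, a, b, kind):
        lo, hi = sorted([a, b])
        assert categorize_velocity(lo, kind).level <= categorize_velocity(hi, kind).level

    def test_low_collision_midrange_is_3_25(self):
        level = categorize_velocity(3.0, Mechanism.COLLISION)
        assert level.midrange_mps == pytest.approx(3.25)

    def test_ground_is_fall_others_collision(self):
        assert mechanism_for_event("ground") is Mechanism.FALL
        assert mechanism_for_event("helmet") is Mechanism.COLLISION


class TestHeadLocation:
    @pytest.mark.parametrize(
        "azimuth,expected",
        [
            (0.0, HeadRegion.FRONT),
            (10.0, HeadRegion.FRONT),
            (350.0, HeadRegion.FRONT),
            (22.5, HeadRegion.FRONT_BOSS),  # boundary goes rearward
            (45.0, HeadRegion.FRONT_BOSS),
            (90.0, HeadRegion.SIDE),
            (270.0, HeadRegion.SIDE),  # left collapses onto right
            (135.0, HeadRegion.REAR_BOSS),
            (180.0, HeadRegion.REAR),
            (170.0, HeadRegion.REAR),
        ],
    )
    def test_sectors(self, azimuth, expected):
        assert assign_head_location(azimuth, 3).location == expected

    def test_crown_overrides_azimuth(self):
        code = assign_head_location(90.0, None, is_top=True)
        assert code.location is HeadRegion.CROWN and code.elevation is None

    def test_elevation_required_when_not_crown(self):
        with pytest.raises(ValueError, match="elevation"):
            assign_head_location(0.0, None)
        with pytest.raises(ValueError, match="elevation"):
            assign_head_location(0.0, 6)

    @given(st.floats(0, 360, exclude_max=True), st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_left_right_mirror_symmetry(self, az, elev):
        assert (
            assign_head_location(az, elev).location
            == assign_head_location(360.0 - az, elev).location
        )
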