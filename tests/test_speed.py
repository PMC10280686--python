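"""Speed computation and the relief-displacement correction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from walkspeed import (
    CameraModel,
    FlightState,
    Homography,
    InvalidInputError,
    PedestrianModel,
    Track,
    TrackPoint,
    corrected_track_speed,
    heading_angle,
    image_point_displacement,
    raw_speed_px,
    relative_displacement,
    speed_correction,
    to_mps,
)

H40 = 40.0
H_PED = 1.7


def _pt(frame, tid, cx, cy, size=15.0):
    return TrackPoint(frame_index=frame, track_id=tid, bbox=(cx - size / 2, cy - size / 2, size, size))


def _translation(tx, ty):
    return Homography(np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1.0]]))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestRelativeDisplacement:
    def test_stationary_under_matching_background(self):
        # background homography equals the camera-induced shift: no net motion
        p1, p2 = _pt(0, 1, 500, 500), _pt(30, 1, 500, 480)
        assert relative_displacement(p1, p2, _translation(0, -20)) == pytest.approx([0, 0])

    def test_hovering_camera(self):
        p1, p2 = _pt(0, 1, 100, 100), _pt(30, 1, 110, 100)
        assert relative_displacement(p1, p2, Homography(np.eye(3))) == pytest.approx([10, 0])

    def test_moving_against_background(self):
        p1, p2 = _pt(0, 1, 500, 500), _pt(30, 1, 490, 500)
        assert relative_displacement(p1, p2, _translation(-20, 0)) == pytest.approx([10, 0])

    def test_mismatched_ids(self):
        with pytest.raises(InvalidInputError):
            relative_displacement(_pt(0, 1, 0, 0), _pt(1, 2, 0, 0), Homography(np.eye(3)))


class TestRawSpeedAndScale:
    @pytest.mark.parametrize(
        "disp, n, fps, expected",
        [((30.0, 0.0), 30, 30.0, 30.0), ((0.0, 0.0), 10, 30.0, 0.0), ((11.3, 0.0), 15, 30.0, 22.6)],
    )
    def test_pixel_speed(self, disp, n, fps, expected):
        assert raw_speed_px(disp, n, fps) == pytest.approx(expected)

    def test_zero_stride_rejected(self):
        with pytest.raises(InvalidInputError):
            raw_speed_px((1.0, 0.0), 0, 30.0)

    def test_to_mps(self, footprint40):
        assert to_mps(30.0, footprint40) == pytest.approx(0.981, abs=1e-3)
        assert to_mps(0.0, footprint40) == 0.0

    def test_scale_doubles_with_altitude(self, camera):
        from walkspeed import ground_footprint

        f40 = ground_footprint(camera, FlightState(altitude_m=40))
        f80 = ground_footprint(camera, FlightState(altitude_m=80))
        assert to_mps(1.0, f80) == pytest.approx(2 * to_mps(1.0, f40), rel=1e-12)


class TestImagePointDisplacement:
    def test_arithmetic(self, flight40):
        assert image_point_displacement(200.0, PedestrianModel(1.7), flight40) == pytest.approx(8.5)
        assert image_point_displacement(200.0, PedestrianModel(0.0), flight40) == 0.0
        assert image_point_displacement(0.0, PedestrianModel(1.7), flight40) == 0.0

    def test_sign_follows_r(self, flight40):
        assert image_point_displacement(-200.0, PedestrianModel(1.7), flight40) == pytest.approx(-8.5)

    def test_height_above_altitude_rejected(self, flight40):
        with pytest.raises(InvalidInputError):
            image_point_displacement(10.0, PedestrianModel(45.0), flight40)


class TestHeadingAngle:
    @pytest.mark.parametrize(
        "point, expected",
        [((960, 100), 0.0), ((1400, 540), 90.0), ((1060, 440), 45.0)],
    )
    def test_reference_points(self, camera, point, expected):
        assert heading_angle(point, camera) == pytest.approx(expected)

    def test_centre_point_degenerate(self, camera):
        assert heading_angle((960.0, 540.0), camera) == 0.0


class TestSpeedCorrection:
    def test_reference_value(self, camera, flight40, footprint40):
        vc = speed_correction(-100, 100, PedestrianModel(1.7), 30, camera, flight40, footprint40, 0.0)
        assert vc == pytest.approx(0.278, abs=1e-3)

    def test_zero_when_r_constant(self, camera, flight40, footprint40, rng):
        for r in rng.uniform(-500, 500, size=5):
            assert speed_correction(r, r, PedestrianModel(1.7), 30, camera, flight40, footprint40, 17.0) == 0.0

    def test_zero_when_walking_perpendicular(self, camera, flight40, footprint40):
        vc = speed_correction(-300, 250, PedestrianModel(1.7), 30, camera, flight40, footprint40, 90.0)
        assert vc == pytest.approx(0.0, abs=1e-12)

    def test_zero_stride_rejected(self, camera, flight40, footprint40):
        with pytest.raises(InvalidInputError):
            speed_correction(0, 1, PedestrianModel(1.7), 0, camera, flight40, footprint40, 0.0)


# ---------------------------------------------------------------------------
# corrected_track_speed on hand-built central-projection scenes
# ---------------------------------------------------------------------------

def _ideal_track(camera, altitude, height, ped_speed, drone_speed, n_frames, start_u=0.0, start_v=0.0):
    """Head track and background homographies for straight-line motion.

    World axis u runs along the flight direction (image up); the head of a
    pedestrian at elevation h is magnified by H/(H-h) about the nadir.
    """
    from walkspeed import ground_footprint

    foot = ground_footprint(camera, FlightState(altitude_m=altitude))
    k = 1.0 / foot.metres_per_pixel
    mag = altitude / (altitude - height)
    x0, y0 = camera.centre
    points, homs = [], {}
    for t in range(n_frames):
        dt = t / camera.fps
        du = (start_u + ped_speed * dt) - drone_speed * dt
        points.append(_pt(t, 1, x0 + start_v * k * mag, y0 - du * k * mag))
        if t:
            shift = drone_speed / camera.fps * k  # ground moves "down" as the drone advances
            homs[(t - 1, t)] = _translation(0.0, shift)
    return Track(track_id=1, points=points), homs


class TestCorrectedTrackSpeed:
    def test_stationary_pedestrian_translating_drone(self, camera, flight40, footprint40):
        track, homs = _ideal_track(camera, H40, H_PED, 0.0, 3.0, 91, start_u=5.0, start_v=2.0)
        est, summary = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        assert est
        # raw speed is biased by the relief sweep, the correction removes it
        assert all(e.raw_speed_m_s > 0.05 for e in est)
        assert summary.median_corrected_m_s <= 0.02

    def test_walker_under_hovering_drone(self, camera, flight40, footprint40):
        track, homs = _ideal_track(camera, H40, H_PED, 1.0, 0.0, 61, start_u=-10.0)
        _, summary = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        assert summary.median_corrected_m_s == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("drone_speed", [3.0, -3.0])
    def test_invariant_to_drone_direction(self, camera, flight40, footprint40, drone_speed):
        track, homs = _ideal_track(camera, H40, H_PED, 1.2, drone_speed, 91, start_u=-8.0)
        _, summary = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        assert summary.median_corrected_m_s == pytest.approx(1.2, abs=0.02)

    def test_zero_height_means_no_correction(self, camera, flight40, footprint40):
        track, homs = _ideal_track(camera, H40, 0.0, 1.5, 4.0, 91)
        est, _ = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(0.0)
        )
        assert est
        for e in est:
            assert e.correction_m_s == 0.0
            assert e.corrected_speed_m_s == pytest.approx(e.raw_speed_m_s, rel=1e-12)

    def test_short_track_yields_empty(self, camera, flight40, footprint40):
        track, homs = _ideal_track(camera, H40, H_PED, 1.0, 0.0, 10)
        est, summary = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        assert est == [] and summary is None

    def test_missing_homography_skips_stride(self, camera, flight40, footprint40):
        track, homs = _ideal_track(camera, H40, H_PED, 1.0, 0.0, 91)
        del homs[(40, 41)]  # breaks the second stride's composition chain
        est, _ = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        assert [e.frame_start for e in est] == [0, 60]

    @given(shift=st.tuples(st.floats(-200, 200), st.floats(-200, 200)))
    def test_invariant_to_global_pixel_translation(self, camera, flight40, footprint40, shift):
        """Translating every pixel coordinate (tracks and homographies alike)
        leaves raw and corrected speeds unchanged."""
        track, homs = _ideal_track(camera, H40, H_PED, 0.8, 2.5, 61, start_u=3.0, start_v=-4.0)
        t = np.array([[1, 0, shift[0]], [0, 1, shift[1]], [0, 0, 1.0]])
        t_inv = np.array([[1, 0, -shift[0]], [0, 1, -shift[1]], [0, 0, 1.0]])
        moved = Track(
            track_id=1,
            points=[
                TrackPoint(p.frame_index, p.track_id, (p.bbox[0] + shift[0], p.bbox[1] + shift[1], p.bbox[2], p.bbox[3]))
                for p in track.points
            ],
        )
        moved_homs = {k: Homography(t @ h.matrix @ t_inv) for k, h in homs.items()}
        base, _ = corrected_track_speed(
            track, homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        shifted, _ = corrected_track_speed(
            moved, moved_homs, camera=camera, flight=flight40, footprint=footprint40, ped=PedestrianModel(H_PED)
        )
        for a, b in zip(base, shifted):
            assert b.raw_speed_m_s == pytest.approx(a.raw_speed_m_s, abs=1e-9)
            assert b.corrected_speed_m_s == pytest.approx(a.corrected_speed_m_s, abs=1e-9)


class TestTrackValidation:
    def test_non_increasing_frames_rejected(self):
        with pytest.raises(InvalidInputError):
            Track(track_id=1, points=[_pt(5, 1, 0, 0), _pt(5, 1, 1, 1)])

    def test_mixed_ids_rejected(self):
        with pytest.raises(InvalidInputError):
            Track(track_id=1, points=[_pt(0, 1, 0, 0), _pt(1, 2, 1, 1)])

    def test_bbox_centre_derivation(self):
        p = TrackPoint(frame_index=0, track_id=3, bbox=(100.0, 200.0, 30.0, 60.0))
        assert p.center == (115.0, 230.0)
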