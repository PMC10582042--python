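"""Spherical planning geometry: rotations, angulation, guide readings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arthroguide.geometry import (
    DegenerateTrajectoryError,
    FrameConvention,
    FrameMismatchError,
    GeometryError,
    GuideReading,
    Point3,
    SphericalAngles,
    angles_from_trajectory,
    direction_from_angles,
    guide_reading,
    is_feasible,
    rotation_y,
    rotation_z,
)


def spherical_components(theta_deg, phi_deg, r):
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array(
        [r * math.cos(p) * math.sin(t), r * math.sin(p) * math.sin(t), r * math.cos(t)]
    )


class TestRotations:
    def test_zero_rotations_are_identity(self):
        assert np.allclose(rotation_z(0).matrix, np.eye(3))
        assert np.allclose(rotation_y(0).matrix, np.eye(3))

    def test_quarter_turns(self):
        assert np.allclose(rotation_z(90).apply([1, 0, 0]), [0, 1, 0])
        assert np.allclose(rotation_y(90).apply([0, 0, 1]), [1, 0, 0])

    def test_entries_match_trigonometric_evaluation(self):
        c, s = math.cos(math.radians(37)), math.sin(math.radians(37))
        assert np.allclose(
            rotation_z(37).matrix, [[c, -s, 0], [s, c, 0], [0, 0, 1]], atol=1e-15
        )
        assert np.allclose(
            rotation_y(37).matrix, [[c, 0, s], [0, 1, 0], [-s, 0, c]], atol=1e-15
        )

    @pytest.mark.parametrize("angle", [-123.4, 0.0, 37.0, 90.0, 180.0, 359.0])
    def test_orthonormality_and_determinant(self, angle):
        for rot in (rotation_z(angle), rotation_y(angle)):
            m = rot.matrix
            assert np.max(np.abs(m.T @ m - np.eye(3))) < 1e-9
            assert abs(np.linalg.det(m) - 1.0) < 1e-9

    def test_non_finite_angle_rejected(self):
        with pytest.raises(GeometryError):
            rotation_z(float("nan"))
        with pytest.raises(GeometryError):
            rotation_y(float("inf"))

    def test_composed_rotation_reproduces_spherical_components(self, rng):
        """R_z(phi)·R_y(theta)·(0,0,r) equals the closed-form components."""
        for _ in range(1000):
            theta = rng.uniform(0, 180)
            phi = rng.uniform(-180, 180)
            r = rng.uniform(0.1, 200)
            got = (rotation_z(phi) @ rotation_y(theta)).apply([0, 0, r])
            assert np.allclose(got, spherical_components(theta, phi, r), atol=1e-9)

    def test_specific_composition_example(self):
        got = (rotation_z(60) @ rotation_y(30)).apply([0, 0, 10])
        want = [
            10 * math.cos(math.radians(60)) * math.sin(math.radians(30)),
            10 * math.sin(math.radians(60)) * math.sin(math.radians(30)),
            10 * math.cos(math.radians(30)),
        ]
        assert np.allclose(got, want, atol=1e-12)


class TestAngulation:
    def test_home_position_tie_break(self):
        target = Point3(3, 4, 5, frame="s")
        entry = Point3(3, 4, 25, frame="s")  # along default home axis (0,0,1)
        a = angles_from_trajectory(entry, target)
        assert a.theta_deg == pytest.approx(0, abs=1e-9)
        assert a.phi_deg == 0.0
        assert a.r_mm == pytest.approx(20)

    def test_equatorial_case(self):
        a = angles_from_trajectory(Point3(10, 0, 0, frame="s"), Point3(0, 0, 0, frame="s"))
        assert a.theta_deg == pytest.approx(90)
        assert a.phi_deg == pytest.approx(0)

    def test_cadaver_t2_trajectory_length(self, study):
        """Second study attempt: pure -y trajectory of 37.82 mm."""
        t2 = study[1]
        a = angles_from_trajectory(t2.entry, t2.target)
        assert a.r_mm == pytest.approx(37.82, abs=1e-9)

    def test_zero_length_trajectory_rejected(self):
        p = Point3(1, 2, 3, frame="s")
        with pytest.raises(DegenerateTrajectoryError):
            angles_from_trajectory(p, Point3(1, 2, 3 + 1e-9, frame="s"))

    def test_frame_mismatch_rejected(self):
        with pytest.raises(FrameMismatchError):
            angles_from_trajectory(Point3(1, 0, 0, frame="a"), Point3(0, 0, 0, frame="b"))

    @settings(max_examples=200, derandomize=True)
    @given(
        theta=st.floats(0.5, 179.5),
        phi=st.floats(-179.9, 180.0),
        r=st.floats(1.0, 300.0),
    )
    def test_angle_direction_round_trip(self, theta, phi, r):
        """angles -> displacement -> angles is the identity off the poles."""
        frame = FrameConvention()
        d = direction_from_angles(SphericalAngles(theta, phi, r), frame)
        target = Point3(0, 0, 0, frame=f"scanner-{frame.axes}")
        entry = Point3(d.dx, d.dy, d.dz, frame=target.frame)
        back = angles_from_trajectory(entry, target, frame)
        assert back.theta_deg == pytest.approx(theta, abs=1e-6)
        assert back.phi_deg == pytest.approx(phi, abs=1e-6) or (
            abs(abs(phi) - 180.0) < 1e-6 and abs(abs(back.phi_deg) - 180.0) < 1e-6
        )
        assert back.r_mm == pytest.approx(r, rel=1e-9)

    def test_forward_evaluation_reproduces_displacement(self):
        v = np.array([3.0, -4.0, 12.0])
        target = Point3(0, 0, 0, frame="scanner-RAS")
        entry = Point3(*v, frame="scanner-RAS")
        a = angles_from_trajectory(entry, target)
        d = direction_from_angles(a, FrameConvention())
        assert np.allclose(d.as_array(), v, rtol=1e-6)

    def test_rigid_frame_invariance(self, rng):
        """A common rotation of points and guide axes leaves (theta, phi, r)
        unchanged."""
        frame = FrameConvention(home_axis=(0.0, 1.0, 0.0))
        entry = Point3(12.0, -30.0, 7.0, frame="s")
        target = Point3(2.0, 1.0, -4.0, frame="s")
        base = angles_from_trajectory(entry, target, frame)
        for _ in range(20):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            e2 = Point3(*(q @ entry.as_array()), frame="s")
            t2 = Point3(*(q @ target.as_array()), frame="s")
            a2 = angles_from_trajectory(e2, t2, frame.transformed(q))
            assert a2.theta_deg == pytest.approx(base.theta_deg, abs=1e-6)
            assert a2.phi_deg == pytest.approx(base.phi_deg, abs=1e-6)
            assert a2.r_mm == pytest.approx(base.r_mm, rel=1e-9)

    def test_custom_home_axis(self):
        frame = FrameConvention(home_axis=(0.0, -1.0, 0.0))
        a = angles_from_trajectory(
            Point3(0, -40, 0, frame="s"), Point3(0, 0, 0, frame="s"), frame
        )
        assert a.theta_deg == pytest.approx(0, abs=1e-9)


class TestGuideReading:
    def test_home_position_reads_zero(self):
        r = guide_reading(SphericalAngles(1e-12, 0, 10))
        assert r.pitch_deg == pytest.approx(0, abs=1e-9)
        assert r.yaw_deg == pytest.approx(0, abs=1e-9)

    def test_in_plane_tilt_reads_theta(self):
        r = guide_reading(SphericalAngles(5, 0, 10))
        assert r.pitch_deg == pytest.approx(5, abs=1e-9)
        assert r.yaw_deg == pytest.approx(0, abs=1e-9)

    def test_diagonal_tilt_splits_by_projection(self):
        r = guide_reading(SphericalAngles(5, 45, 10))
        want = math.degrees(math.atan(math.tan(math.radians(5)) * math.cos(math.radians(45))))
        assert r.pitch_deg == pytest.approx(want, abs=1e-9)
        assert r.yaw_deg == pytest.approx(want, abs=1e-9)

    def test_right_angle_tilt_is_out_of_range_not_an_overflow(self):
        r = guide_reading(SphericalAngles(90, 0, 10))
        assert math.isfinite(r.pitch_deg)
        assert not r.feasible

    def test_feasibility_boundary_and_margins(self):
        ok = is_feasible(GuideReading(0, 0, limit_deg=6))
        assert ok.feasible and ok.pitch_margin_deg == 6
        bad = is_feasible(GuideReading(6.01, 0, limit_deg=6))
        assert not bad.feasible and bad.pitch_margin_deg == pytest.approx(-0.01)

    def test_future_wider_guide_range(self):
        assert is_feasible(GuideReading(3, 3, limit_deg=35)).feasible

    def test_limit_must_be_positive(self):
        with pytest.raises(GeometryError):
            GuideReading(0, 0, limit_deg=0)


class TestTypes:
    def test_point_requires_finite_coordinates_and_frame(self):
        with pytest.raises(GeometryError):
            Point3(float("nan"), 0, 0)
        with pytest.raises(GeometryError):
            Point3(0, 0, 0, frame="")

    def test_spherical_angle_ranges_enforced(self):
        with pytest.raises(GeometryError):
            SphericalAngles(-1, 0, 10)
        with pytest.raises(GeometryError):
            SphericalAngles(10, 0, -1)
        with pytest.raises(GeometryError):
            SphericalAngles(10, -180.0, 1)

    def test_displacement_magnitude_is_euclidean_norm(self):
        from arthroguide.geometry import Displacement

        d = Displacement(3, 4, 12)
        assert d.r == pytest.approx(13.0, rel=1e-9)
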