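"""Spherical-coordinate needle-angulation planning.

The planning problem: a radiologist picks an entry point on the skin (on the
grid template) and a target point inside the joint on MR images, both in
scanner millimetre coordinates.  The guidance device holds the needle along a
"home" axis and is tilted by a polar angle ``theta`` and azimuth ``phi``; a
spherical bubble level reads the tilt as *pitch* and *yaw*.  This module
converts entry/target pairs to ``(theta, phi, r)`` with the origin at the
target, decomposes the tilt into pitch/yaw readings, and checks them against
the guide's mechanical range (±6° in the studied device, ±35° planned).

Convention: the displacement vector from target to entry, expressed in the
guide frame, is

    r_x = r cos(phi) sin(theta)
    r_y = r sin(phi) sin(theta)
    r_z = r cos(theta)

i.e. ``R_z(phi) · R_y(theta)`` applied to ``(0, 0, r)``.  Angles are degrees
at every public interface and radians only inside function bodies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Point3",
    "Displacement",
    "SphericalAngles",
    "Rotation",
    "GuideReading",
    "FeasibilityReport",
    "FrameConvention",
    "GeometryError",
    "FrameMismatchError",
    "DegenerateTrajectoryError",
    "rotation_z",
    "rotation_y",
    "angles_from_trajectory",
    "direction_from_angles",
    "guide_reading",
    "is_feasible",
]

#: Mechanical half-range of the studied hand-held guide, degrees.
DEFAULT_GUIDE_LIMIT_DEG = 6.0
#: Planned half-range of the next device revision, degrees.
PLANNED_GUIDE_LIMIT_DEG = 35.0


class GeometryError(ValueError):
    """Invalid geometric input."""


class FrameMismatchError(GeometryError):
    """Points from different coordinate frames were combined."""


class DegenerateTrajectoryError(GeometryError):
    """Entry and target coincide; the trajectory direction is undefined."""


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise GeometryError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class Point3:
    """A labelled 3D position in millimetres within a named coordinate frame."""

    x: float
    y: float
    z: float
    frame: str = "scanner-RAS"
    label: str = ""

    def __post_init__(self) -> None:
        _check_finite("coordinate", self.x, self.y, self.z)
        if not self.frame:
            raise GeometryError("frame label must be non-empty")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Point3") -> float:
        self.require_same_frame(other)
        return float(np.linalg.norm(self.as_array() - other.as_array()))

    def require_same_frame(self, other: "Point3") -> None:
        if self.frame != other.frame:
            raise FrameMismatchError(
                f"frames differ: {self.frame!r} vs {other.frame!r}"
            )


@dataclass(frozen=True)
class Displacement:
    """A millimetre displacement vector; ``r`` is its Euclidean magnitude."""

    dx: float
    dy: float
    dz: float
    frame: str = "guide"

    def __post_init__(self) -> None:
        _check_finite("displacement", self.dx, self.dy, self.dz)

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.as_array()))

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz], dtype=float)


@dataclass(frozen=True)
class SphericalAngles:
    """Needle angulation: polar tilt ``theta``, azimuth ``phi``, depth ``r``.

    ``theta`` is the angle from the guide's home axis in [0, 180] degrees,
    ``phi`` the azimuth in (−180, 180] degrees, ``r`` the entry-to-target
    distance in millimetres (> 0).
    """

    theta_deg: float
    phi_deg: float
    r_mm: float

    def __post_init__(self) -> None:
        _check_finite("angle", self.theta_deg, self.phi_deg, self.r_mm)
        if not 0.0 <= self.theta_deg <= 180.0:
            raise GeometryError(f"theta must lie in [0, 180], got {self.theta_deg}")
        if not -180.0 < self.phi_deg <= 180.0:
            raise GeometryError(f"phi must lie in (-180, 180], got {self.phi_deg}")
        if self.r_mm <= 0.0:
            raise GeometryError(f"r must be positive, got {self.r_mm}")


@dataclass(frozen=True)
class Rotation:
    """A proper rotation matrix (orthonormal, det +1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise GeometryError(f"rotation matrix must be 3x3, got {m.shape}")
        if np.max(np.abs(m.T @ m - np.eye(3))) > 1e-9:
            raise GeometryError("matrix is not orthonormal")
        if abs(np.linalg.det(m) - 1.0) > 1e-9:
            raise GeometryError("matrix is not a proper rotation (det != +1)")
        object.__setattr__(self, "matrix", m)

    def apply(self, v: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(v, dtype=float)

    def __matmul__(self, other: "Rotation") -> "Rotation":
        return Rotation(self.matrix @ other.matrix)


@dataclass(frozen=True)
class GuideReading:
    """Bubble-level tilt readings with the guide's symmetric half-range."""

    pitch_deg: float
    yaw_deg: float
    limit_deg: float = DEFAULT_GUIDE_LIMIT_DEG

    def __post_init__(self) -> None:
        if self.limit_deg <= 0:
            raise GeometryError(f"limit must be positive, got {self.limit_deg}")

    @property
    def feasible(self) -> bool:
        return (
            abs(self.pitch_deg) <= self.limit_deg
            and abs(self.yaw_deg) <= self.limit_deg
        )


@dataclass(frozen=True)
class FeasibilityReport:
    """Per-axis margins to the guide's range; positive margin = inside range."""

    feasible: bool
    pitch_deg: float
    yaw_deg: float
    limit_deg: float
    pitch_margin_deg: float
    yaw_margin_deg: float


def _complete_basis(home_axis: np.ndarray, azimuth_axis: np.ndarray | None) -> np.ndarray:
    """Orthonormal guide basis as columns (x=azimuth-zero, y, z=home)."""
    gz = np.asarray(home_axis, dtype=float)
    nz = np.linalg.norm(gz)
    if abs(nz - 1.0) > 1e-9:
        raise GeometryError(f"home axis must be unit norm, |v| = {nz}")
    gz = gz / nz
    if azimuth_axis is None:
        # Deterministic completion: project scanner x (or y if near-parallel)
        # onto the plane normal to the home axis.
        ref = np.array([1.0, 0.0, 0.0])
        if abs(gz @ ref) > 1.0 - 1e-9:
            ref = np.array([0.0, 1.0, 0.0])
        azimuth_axis = ref
    gx = np.asarray(azimuth_axis, dtype=float)
    gx = gx - (gx @ gz) * gz
    n = np.linalg.norm(gx)
    if n < 1e-12:
        raise GeometryError("azimuth axis is parallel to the home axis")
    gx = gx / n
    gy = np.cross(gz, gx)
    return np.column_stack([gx, gy, gz])


@dataclass(frozen=True)
class FrameConvention:
    """Scanner axis convention plus the guide's home direction.

    ``home_axis`` is the needle direction when the guide reads zero tilt,
    expressed in scanner coordinates (default: scanner z, i.e. superior in
    RAS).  ``azimuth_axis`` fixes where azimuth phi = 0 points; when omitted
    it is completed deterministically from the scanner x axis.
    """

    axes: str = "RAS"
    home_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    azimuth_axis: tuple[float, float, float] | None = None
    _basis: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.axes not in ("RAS", "LPS"):
            raise GeometryError(f"axes must be 'RAS' or 'LPS', got {self.axes!r}")
        az = None if self.azimuth_axis is None else np.asarray(self.azimuth_axis)
        basis = _complete_basis(np.asarray(self.home_axis, dtype=float), az)
        object.__setattr__(self, "_basis", basis)

    @property
    def basis(self) -> np.ndarray:
        """Columns are the guide x, y, z axes in scanner coordinates."""
        return self._basis.copy()

    def to_guide(self, v: np.ndarray) -> np.ndarray:
        return self._basis.T @ np.asarray(v, dtype=float)

    def to_scanner(self, v: np.ndarray) -> np.ndarray:
        return self._basis @ np.asarray(v, dtype=float)

    def transformed(self, rotation: np.ndarray) -> "FrameConvention":
        """The same convention after a rigid rotation of the scanner frame."""
        q = np.asarray(rotation, dtype=float)
        return replace(
            self,
            home_axis=tuple(q @ self._basis[:, 2]),
            azimuth_axis=tuple(q @ self._basis[:, 0]),
        )


def rotation_z(phi_deg: float) -> Rotation:
    """Rotation by ``phi`` degrees about the z axis."""
    _check_finite("phi", phi_deg)
    p = math.radians(phi_deg)
    c, s = math.cos(p), math.sin(p)
    return Rotation(np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]]))


def rotation_y(theta_deg: float) -> Rotation:
    """Rotation by ``theta`` degrees about the y axis.

    This is the standard y-axis rotation, the unique choice for which
    ``rotation_z(phi) @ rotation_y(theta)`` maps ``(0, 0, r)`` to
    ``(r cos phi sin theta, r sin phi sin theta, r cos theta)``.
    """
    _check_finite("theta", theta_deg)
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return Rotation(np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]]))


def angles_from_trajectory(
    entry: Point3,
    target: Point3,
    frame: FrameConvention | None = None,
    min_separation_mm: float = 1e-6,
) -> SphericalAngles:
    """Needle angulation for a planned entry/target pair.

    The spherical origin sits at the target; the entry lies at ``(r, theta,
    phi)`` in the guide frame.  When the trajectory is along the home axis
    (``sin theta = 0``) the azimuth is undefined and fixed to ``phi = 0``.
    """
    frame = frame or FrameConvention()
    entry.require_same_frame(target)
    d = entry.as_array() - target.as_array()
    r = float(np.linalg.norm(d))
    if r <= min_separation_mm:
        raise DegenerateTrajectoryError(
            f"entry and target separated by {r:g} mm (<= {min_separation_mm:g})"
        )
    v = frame.to_guide(d)
    theta = math.degrees(math.acos(max(-1.0, min(1.0, v[2] / r))))
    if math.hypot(v[0], v[1]) < 1e-12 * r:
        phi = 0.0  # azimuth undefined on the pole; deterministic tie-break
    else:
        phi = math.degrees(math.atan2(v[1], v[0]))
    if phi <= -180.0:
        phi = 180.0
    return SphericalAngles(theta_deg=theta, phi_deg=phi, r_mm=r)


def direction_from_angles(
    angles: SphericalAngles, frame: FrameConvention | None = None
) -> Displacement:
    """Target-to-entry displacement for given angulation.

    Returned in guide coordinates, or in scanner coordinates when a
    ``frame`` is supplied.
    """
    t = math.radians(angles.theta_deg)
    p = math.radians(angles.phi_deg)
    r = angles.r_mm
    v = np.array(
        [r * math.cos(p) * math.sin(t), r * math.sin(p) * math.sin(t), r * math.cos(t)]
    )
    if frame is None:
        return Displacement(*v, frame="guide")
    w = frame.to_scanner(v)
    return Displacement(*w, frame=f"scanner-{frame.axes}")


def guide_reading(
    angles: SphericalAngles, limit_deg: float = DEFAULT_GUIDE_LIMIT_DEG
) -> GuideReading:
    """Decompose the angulation into the bubble level's pitch/yaw tilts.

    Projection convention: ``pitch = atan(tan theta · cos phi)`` and
    ``yaw = atan(tan theta · sin phi)``, evaluated via atan2 so that a tilt
    at or beyond 90° yields a finite, necessarily out-of-range reading
    instead of hitting the tangent singularity.
    """
    t = math.radians(angles.theta_deg)
    p = math.radians(angles.phi_deg)
    pitch = math.degrees(math.atan2(math.sin(t) * math.cos(p), math.cos(t)))
    yaw = math.degrees(math.atan2(math.sin(t) * math.sin(p), math.cos(t)))
    return GuideReading(pitch_deg=pitch, yaw_deg=yaw, limit_deg=limit_deg)


def is_feasible(reading: GuideReading) -> FeasibilityReport:
    """Check a reading against the guide's mechanical range, with margins."""
    pm = reading.limit_deg - abs(reading.pitch_deg)
    ym = reading.limit_deg - abs(reading.yaw_deg)
    return FeasibilityReport(
        feasible=reading.feasible,
        pitch_deg=reading.pitch_deg,
        yaw_deg=reading.yaw_deg,
        limit_deg=reading.limit_deg,
        pitch_margin_deg=pm,
        yaw_margin_deg=ym,
    )
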