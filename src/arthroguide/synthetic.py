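"""Synthetic inputs with the statistical structure the toolkit assumes.

Three generators, all seed-deterministic:

* :func:`simulate_needle_points` — points picked along a needle image
  artifact: uniformly spaced samples along a straight line that is laterally
  displaced from the planned entry→target trajectory by a known offset, with
  isotropic Gaussian picking jitter per point.  The planted offset is the
  ground-truth normal target-to-needle distance.
* :func:`simulate_targeting_study` — a whole targeting study with an
  additive, independent error budget: 2D isotropic template slip
  perpendicular to the trajectory, quantization of the guide's tilt
  reading, and depth error along the needle.
* :func:`render_grid_volume` — a voxelized slab carrying a grid pattern as
  intensity modulation, on a flat or cylindrical surface, written as NIfTI
  when needed.  A stand-in for the template's appearance on T1-weighted
  images: intensity plus Gaussian noise only, no MR physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .evaluation import NeedleObservation
from .geometry import GeometryError, Point3
from .grid import GridError, GridPattern

__all__ = [
    "NeedleSimSpec",
    "StudySimSpec",
    "GridVolumeSpec",
    "simulate_needle_points",
    "simulate_targeting_study",
    "render_grid_volume",
    "sample_cells_from_volume",
    "save_volume_nifti",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length vector")
    return v / n


def _perp_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair spanning the plane normal to direction."""
    d = _unit(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 1.0 - 1e-9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, ref))
    v = np.cross(d, u)
    return u, v


@dataclass(frozen=True)
class NeedleSimSpec:
    """One simulated needle insertion.

    ``offset_mm`` is a systematic lateral placement error: the realised
    needle line is the planned line shifted by exactly this distance in a
    seeded random azimuth perpendicular to the trajectory.  ``n_points``
    defaults to a uniform draw in [10, 20], matching typical manual artifact
    picking; ``jitter_mm`` is the isotropic per-point picking noise.
    """

    entry: Point3
    target: Point3
    offset_mm: float = 0.0
    n_points: int | None = None
    jitter_mm: float = 0.0
    seed: int = 0
    overshoot_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.offset_mm < 0:
            raise GeometryError("offset must be >= 0")
        if self.jitter_mm < 0:
            raise GeometryError("jitter sigma must be >= 0")
        if self.n_points is not None and not 2 <= self.n_points <= 100:
            raise GeometryError("n_points must lie in [2, 100]")


def simulate_needle_points(spec: NeedleSimSpec) -> NeedleObservation:
    """Sample artifact points along the (displaced) needle line."""
    rng = np.random.default_rng(spec.seed)
    e, t = spec.entry.as_array(), spec.target.as_array()
    axis = t - e
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise GeometryError("entry and target coincide")
    d = axis / length
    u, v = _perp_basis(d)
    az = rng.uniform(0.0, 2.0 * math.pi)
    shift = spec.offset_mm * (math.cos(az) * u + math.sin(az) * v)
    n = spec.n_points if spec.n_points is not None else int(rng.integers(10, 21))
    # Uniform spacing from the skin to just past the target depth.
    ts = np.linspace(0.0, 1.0 + spec.overshoot_frac, n)
    pts = e + shift + np.outer(ts * length, d)
    if spec.jitter_mm > 0:
        pts = pts + rng.normal(0.0, spec.jitter_mm, size=pts.shape)
    frame = spec.entry.frame
    return NeedleObservation(
        points=tuple(
            Point3(*p, frame=frame, label=f"artifact-{i}") for i, p in enumerate(pts)
        ),
        attempt=spec.entry.label or "sim",
    )


@dataclass(frozen=True)
class StudySimSpec:
    """Error budget for a whole simulated targeting study.

    Independent additive error sources, all optional:

    * ``grid_sigma_mm`` — 2D isotropic Gaussian displacement of the entry
      point in the plane perpendicular to the trajectory (template slip and
      stretch).  Alone, it makes the normal distance Rayleigh-distributed
      with mean sigma·sqrt(pi/2).
    * ``angle_step_deg`` — the guide's tilt resolution; the polar tilt is
      rounded to the nearest step, bounding the miss by depth·tan(step/2).
    * ``depth_sigma_mm`` — insertion-depth error along the needle axis; it
      moves the tip but not the needle *line*, so it leaves the normal
      target-to-line distance unchanged.
    """

    n_attempts: int = 5
    grid_sigma_mm: float = 0.0
    angle_step_deg: float = 0.0
    depth_sigma_mm: float = 0.0
    jitter_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_attempts < 1:
            raise GeometryError("need at least one attempt")
        for s in (self.grid_sigma_mm, self.angle_step_deg, self.depth_sigma_mm, self.jitter_mm):
            if s < 0:
                raise GeometryError("error-budget sigmas must be >= 0")


def simulate_targeting_study(
    spec: StudySimSpec,
    trajectories: Sequence[tuple[Point3, Point3]],
) -> list[tuple[NeedleObservation, Point3, Point3]]:
    """Simulate attempts over planned trajectories, cycling when needed.

    Returns (observation, planned entry, planned target) triples ready for
    :func:`arthroguide.evaluation.targeting_error`.  With every error knob
    at zero all normal distances are exactly zero.
    """
    if not trajectories:
        raise GeometryError("need at least one planned trajectory")
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n_attempts):
        entry, target = trajectories[i % len(trajectories)]
        e, t = entry.as_array(), target.as_array()
        d = _unit(t - e)
        depth = float(np.linalg.norm(t - e))
        u, v = _perp_basis(d)
        # Template slip: entry moves in the perpendicular plane, aim direction
        # is preserved, so the whole needle line shifts laterally.
        e_real = e.copy()
        if spec.grid_sigma_mm > 0:
            slip = rng.normal(0.0, spec.grid_sigma_mm, size=2)
            e_real = e_real + slip[0] * u + slip[1] * v
        d_real = d
        if spec.angle_step_deg > 0:
            # The guide reads the tilt in steps: rotate the aim direction in a
            # seeded random plane through the trajectory by the rounding
            # residual of the tilt angle, |delta| <= step/2.
            frac = rng.uniform(-0.5, 0.5)
            delta = math.radians(frac * spec.angle_step_deg)
            az = rng.uniform(0.0, 2.0 * math.pi)
            w = math.cos(az) * u + math.sin(az) * v
            d_real = _unit(math.cos(delta) * d + math.sin(delta) * w)
        t_real = e_real + depth * d_real
        if spec.depth_sigma_mm > 0:
            t_real = t_real + rng.normal(0.0, spec.depth_sigma_mm) * d_real
        needle_spec = NeedleSimSpec(
            entry=Point3(*e_real, frame=entry.frame, label=f"a{i}-entry"),
            target=Point3(*t_real, frame=entry.frame, label=f"a{i}-target"),
            jitter_mm=spec.jitter_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        obs = simulate_needle_points(needle_spec)
        obs = NeedleObservation(points=obs.points, attempt=f"attempt-{i}")
        out.append((obs, entry, target))
    return out


@dataclass(frozen=True)
class GridVolumeSpec:
    """Voxelized rendering of a patterned slab.

    The pattern modulates voxel intensity between ``background`` and
    ``foreground`` linearly in the symbol value.  ``surface`` is ``"flat"``
    (slab in the xy plane, thickness along z) or ``"cylinder"`` (slab
    wrapped around a cylinder whose axis runs along x; the pattern's row
    coordinate maps to arc length).
    """

    pattern: GridPattern
    surface: Literal["flat", "cylinder"] = "flat"
    cylinder_radius_mm: float = 50.0
    voxel_mm: float = 1.0
    slab_mm: float = 3.0
    foreground: float = 100.0
    background: float = 10.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise GeometryError("voxel size must be positive")
        if self.voxel_mm > self.pattern.pitch_mm:
            raise GridError(
                f"voxel size {self.voxel_mm} mm exceeds cell pitch "
                f"{self.pattern.pitch_mm} mm: pattern unresolvable"
            )
        if self.slab_mm <= 0:
            raise GeometryError("slab thickness must be positive")
        if self.surface == "cylinder" and self.cylinder_radius_mm <= self.slab_mm:
            raise GeometryError("cylinder radius must exceed slab thickness")
        if self.noise_sigma < 0:
            raise GeometryError("noise sigma must be >= 0")


def _symbol_intensity(spec: GridVolumeSpec, cells: np.ndarray) -> np.ndarray:
    amax = max(spec.pattern.alphabet - 1, 1)
    return spec.background + (spec.foreground - spec.background) * cells / amax


def render_grid_volume(spec: GridVolumeSpec) -> np.ndarray:
    """Render the patterned slab into a 3D intensity array (x, y, z order)."""
    pat = spec.pattern
    pitch, vox = pat.pitch_mm, spec.voxel_mm
    rng = np.random.default_rng(spec.seed)
    nx = int(math.ceil(pat.cols * pitch / vox))
    ny = int(math.ceil(pat.rows * pitch / vox))
    nz_slab = max(1, int(round(spec.slab_mm / vox)))
    if spec.surface == "flat":
        nz = nz_slab + 2  # one background layer each side
        vol = np.full((nx, ny, nz), spec.background, dtype=float)
        xs = (np.arange(nx) + 0.5) * vox
        ys = (np.arange(ny) + 0.5) * vox
        ci = np.clip((xs / pitch).astype(int), 0, pat.cols - 1)
        ri = np.clip((ys / pitch).astype(int), 0, pat.rows - 1)
        sheet = _symbol_intensity(spec, pat.cells[np.ix_(ri, ci)]).T  # (nx, ny)
        vol[:, :, 1 : 1 + nz_slab] = sheet[:, :, None]
    else:
        # Cylinder axis along x; pattern columns map to x, rows to arc length.
        R = spec.cylinder_radius_mm
        arc_total = pat.rows * pitch
        half_angle = arc_total / (2 * R)
        if half_angle > math.pi:
            raise GeometryError("pattern arc exceeds cylinder circumference")
        extent = R + spec.slab_mm
        ny = nz = int(math.ceil(2 * extent / vox))
        vol = np.full((nx, ny, nz), spec.background, dtype=float)
        ys = (np.arange(ny) + 0.5) * vox - extent
        zs = (np.arange(nz) + 0.5) * vox - extent
        yy, zz = np.meshgrid(ys, zs, indexing="ij")
        rad = np.hypot(yy, zz)
        ang = np.arctan2(yy, zz)  # zero at +z, the slab's crown
        in_slab = (rad >= R) & (rad < R + spec.slab_mm) & (np.abs(ang) < half_angle)
        arc = (ang + half_angle) * R
        ri = np.clip((arc / pitch).astype(int), 0, pat.rows - 1)
        xs = (np.arange(nx) + 0.5) * vox
        ci = np.clip((xs / pitch).astype(int), 0, pat.cols - 1)
        for ix in range(nx):
            sheet = _symbol_intensity(spec, pat.cells[ri, ci[ix]])
            vol[ix][in_slab] = sheet[in_slab]
    if spec.noise_sigma > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma, size=vol.shape)
    return vol


def sample_cells_from_volume(spec: GridVolumeSpec, vol: np.ndarray) -> np.ndarray:
    """Recover the symbol array of a *flat* rendering by cell-centre sampling.

    Samples the slab mid-plane at each cell centre and inverts the linear
    symbol→intensity map by nearest symbol.
    """
    if spec.surface != "flat":
        raise GeometryError("cell-centre sampling is defined for flat renderings")
    pat = spec.pattern
    vox = spec.voxel_mm
    nz_slab = max(1, int(round(spec.slab_mm / vox)))
    iz = 1 + nz_slab // 2
    xs = ((np.arange(pat.cols) + 0.5) * pat.pitch_mm / vox).astype(int)
    ys = ((np.arange(pat.rows) + 0.5) * pat.pitch_mm / vox).astype(int)
    xs = np.clip(xs, 0, vol.shape[0] - 1)
    ys = np.clip(ys, 0, vol.shape[1] - 1)
    vals = vol[np.ix_(xs, ys)][:, :, iz].T  # (rows, cols)
    amax = max(pat.alphabet - 1, 1)
    sym = (vals - spec.background) / (spec.foreground - spec.background) * amax
    return np.clip(np.rint(sym), 0, pat.alphabet - 1).astype(np.int64)


def save_volume_nifti(spec: GridVolumeSpec, vol: np.ndarray, path) -> None:
    """Write the volume as NIfTI with an isotropic voxel-size affine."""
    import nibabel as nib

    affine = np.diag([spec.voxel_mm, spec.voxel_mm, spec.voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
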