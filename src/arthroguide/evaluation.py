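"""Targeting-accuracy evaluation.

The accuracy metric of the cadaver study: 10–20 points are picked along the
needle's image artifact, a straight 3D line is fitted to them by total least
squares (principal right-singular vector of the centred point matrix), and
the attempt's error is the perpendicular Euclidean distance from the planned
target point to that line.  Study-level accuracy is the mean ± sample
standard deviation of the per-attempt distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import FrameMismatchError, GeometryError, Point3

__all__ = [
    "NeedleObservation",
    "FittedLine",
    "TargetingResult",
    "AccuracySummary",
    "fit_line",
    "point_line_distance",
    "targeting_error",
    "summarize",
]

# Relative gap below which the two leading singular values are treated as
# tied and the direction is chosen by the deterministic tie-break.
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class NeedleObservation:
    """Points sampled along a needle artifact, all in one frame."""

    points: tuple[Point3, ...]
    attempt: str = ""

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        if len(pts) < 2:
            raise GeometryError("an observation needs at least 2 points")
        for p in pts[1:]:
            pts[0].require_same_frame(p)
        object.__setattr__(self, "points", pts)

    @property
    def frame(self) -> str:
        return self.points[0].frame

    def as_array(self) -> np.ndarray:
        return np.array([p.as_array() for p in self.points])


@dataclass(frozen=True)
class FittedLine:
    """Total-least-squares line: centroid anchor, unit direction, rms residual."""

    anchor: Point3
    direction: tuple[float, float, float]
    rms_mm: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise GeometryError("direction must be unit norm")
        if self.rms_mm < 0:
            raise GeometryError("rms residual must be non-negative")
        object.__setattr__(self, "direction", tuple(float(x) for x in d))

    @property
    def frame(self) -> str:
        return self.anchor.frame


@dataclass(frozen=True)
class TargetingResult:
    attempt: str
    planned_entry: Point3
    planned_target: Point3
    normal_distance_mm: float

    def __post_init__(self) -> None:
        if self.normal_distance_mm < 0:
            raise GeometryError("distance must be non-negative")


@dataclass(frozen=True)
class AccuracySummary:
    """Study summary: n attempts, mean and sample (n−1) SD in millimetres."""

    n: int
    mean_mm: float
    sd_mm: float | None


def _tie_break_direction(candidates: np.ndarray) -> np.ndarray:
    """Pick among near-equal principal directions: lexicographically largest
    absolute components, deterministic across SVD sign conventions."""
    key = sorted(range(len(candidates)), key=lambda i: tuple(np.abs(candidates[i])))
    return candidates[key[-1]]


def _canonical_sign(d: np.ndarray) -> np.ndarray:
    i = int(np.argmax(np.abs(d)))
    return d if d[i] > 0 else -d


def fit_line(obs: NeedleObservation) -> FittedLine:
    """Fit the total-least-squares 3D line through the observation points.

    The direction is the principal right-singular vector of the centred
    point matrix, which minimises the sum of squared perpendicular
    residuals over all lines.  An isotropic cloud (tied leading singular
    values) is flagged ``degenerate`` and resolved deterministically.
    """
    pts = obs.as_array()
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if not np.any(np.linalg.norm(centred, axis=1) > 1e-12):
        raise GeometryError("all observation points coincide")
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    degenerate = len(s) > 1 and s[1] >= s[0] * (1.0 - _DEGENERACY_RTOL)
    if degenerate:
        tied = vt[s >= s[0] * (1.0 - _DEGENERACY_RTOL)]
        direction = _tie_break_direction(tied)
    else:
        direction = vt[0]
    direction = _canonical_sign(direction / np.linalg.norm(direction))
    resid = centred - np.outer(centred @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    anchor = Point3(*centroid, frame=obs.frame, label=f"{obs.attempt}-centroid")
    return FittedLine(
        anchor=anchor, direction=tuple(direction), rms_mm=rms, degenerate=degenerate
    )


def point_line_distance(line: FittedLine, p: Point3) -> float:
    """Perpendicular distance from ``p`` to the line, ‖(p − a) × d‖."""
    if line.frame != p.frame:
        raise FrameMismatchError(f"frames differ: {line.frame!r} vs {p.frame!r}")
    v = p.as_array() - line.anchor.as_array()
    return float(np.linalg.norm(np.cross(v, np.asarray(line.direction))))


def targeting_error(
    obs: NeedleObservation, planned_entry: Point3, planned_target: Point3
) -> TargetingResult:
    """Normal target-to-needle distance for one attempt."""
    planned_entry.require_same_frame(planned_target)
    line = fit_line(obs)
    if line.frame != planned_target.frame:
        raise FrameMismatchError(
            f"observation frame {line.frame!r} != planned frame "
            f"{planned_target.frame!r}"
        )
    d = point_line_distance(line, planned_target)
    return TargetingResult(
        attempt=obs.attempt,
        planned_entry=planned_entry,
        planned_target=planned_target,
        normal_distance_mm=d,
    )


def summarize(results: Sequence[TargetingResult | float]) -> AccuracySummary:
    """Mean and sample SD of per-attempt normal distances.

    Accepts results or bare distances.  The SD uses the n−1 denominator and
    is ``None`` for a single attempt.
    """
    if len(results) == 0:
        raise GeometryError("cannot summarise an empty result list")
    d = np.array(
        [
            r.normal_distance_mm if isinstance(r, TargetingResult) else float(r)
            for r in results
        ]
    )
    sd = float(d.std(ddof=1)) if len(d) >= 2 else None
    return AccuracySummary(n=len(d), mean_mm=float(d.mean()), sd_mm=sd)
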