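"""End-to-end planning → guidance → confirmation → evaluation workflow.

Mirrors the in-bore procedure: plan the angulation from the chosen entry
and target, read pitch/yaw on the guide and check feasibility, insert (here:
simulate the confirmation observation), and evaluate the normal
target-to-needle distance.  Every run emits a reproducibility manifest with
the full configuration, seed and library versions.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .evaluation import summarize, targeting_error
from .geometry import (
    DEFAULT_GUIDE_LIMIT_DEG,
    FrameConvention,
    Point3,
    angles_from_trajectory,
    guide_reading,
    is_feasible,
)
from .markups import read_markups
from .synthetic import NeedleSimSpec, simulate_needle_points
from .tables import write_results_table

__all__ = ["RunConfig", "PlanRecord", "plan_trajectory", "run_workflow"]


class RunConfig(BaseModel):
    """Validated workflow configuration; all defaults documented here."""

    entry_file: str
    target_file: str
    entry_labels: list[str] = Field(default_factory=list)  # empty = all, paired in order
    target_labels: list[str] = Field(default_factory=list)
    home_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    guide_limit_deg: float = Field(default=DEFAULT_GUIDE_LIMIT_DEG, gt=0)
    simulate_confirmation: bool = True
    sim_offset_mm: float = Field(default=0.0, ge=0)
    sim_jitter_mm: float = Field(default=0.0, ge=0)
    seed: int = 0
    out_dir: str = "arthroguide-run"


@dataclass(frozen=True)
class PlanRecord:
    """One planned trajectory with its guide reading and feasibility."""

    label: str
    theta_deg: float
    phi_deg: float
    r_mm: float
    pitch_deg: float
    yaw_deg: float
    limit_deg: float
    feasible: bool

    def to_json_dict(self) -> dict:
        return asdict(self)


def plan_trajectory(
    entry: Point3,
    target: Point3,
    frame: FrameConvention | None = None,
    limit_deg: float = DEFAULT_GUIDE_LIMIT_DEG,
) -> PlanRecord:
    angles = angles_from_trajectory(entry, target, frame)
    reading = guide_reading(angles, limit_deg=limit_deg)
    report = is_feasible(reading)
    return PlanRecord(
        label=entry.label or target.label,
        theta_deg=angles.theta_deg,
        phi_deg=angles.phi_deg,
        r_mm=angles.r_mm,
        pitch_deg=reading.pitch_deg,
        yaw_deg=reading.yaw_deg,
        limit_deg=reading.limit_deg,
        feasible=report.feasible,
    )


def _manifest(config: RunConfig) -> dict:
    return {
        "tool": "arthroguide",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.model_dump(),
    }


def run_workflow(config: RunConfig) -> dict:
    """Run planning + (simulated) confirmation + evaluation; write artifacts.

    Returns a dict with plans, per-attempt results and the accuracy summary;
    the same content is written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entry_doc = read_markups(config.entry_file)
    target_doc = read_markups(config.target_file)
    entry_labels = list(config.entry_labels) or list(entry_doc.labels())
    target_labels = list(config.target_labels) or list(target_doc.labels())
    if len(entry_labels) != len(target_labels):
        raise ValueError(
            f"{len(entry_labels)} entry labels vs {len(target_labels)} target labels"
        )
    frame = FrameConvention(home_axis=config.home_axis)
    rng = np.random.default_rng(config.seed)

    plans, results = [], []
    for el, tl in zip(entry_labels, target_labels):
        entry, target = entry_doc.get(el), target_doc.get(tl)
        plan = plan_trajectory(entry, target, frame, config.guide_limit_deg)
        plans.append(plan)
        if config.simulate_confirmation:
            spec = NeedleSimSpec(
                entry=entry,
                target=target,
                offset_mm=config.sim_offset_mm,
                jitter_mm=config.sim_jitter_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            obs = simulate_needle_points(spec)
            results.append(targeting_error(obs, entry, target))

    report: dict = {
        "plans": [p.to_json_dict() for p in plans],
        "all_feasible": all(p.feasible for p in plans),
    }
    if results:
        s = summarize(results)
        report["summary"] = {"n": s.n, "mean_mm": s.mean_mm, "sd_mm": s.sd_mm}
        write_results_table(results, out / "results.csv")
    (out / "plans.json").write_text(json.dumps(report, indent=2))
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    return report
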