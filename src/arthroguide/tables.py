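"""Results tables mirroring the study report layout.

One row per targeting attempt: the desired entry point, the desired target
point, and the normal target-to-needle distance, all in millimetres.
Distances are kept at full precision in memory and formatted only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluation import AccuracySummary, TargetingResult, summarize
from .geometry import GeometryError

__all__ = ["results_to_frame", "write_results_table", "read_results_table"]

_COLUMNS = [
    "attempt",
    "entry_x_mm", "entry_y_mm", "entry_z_mm",
    "target_x_mm", "target_y_mm", "target_z_mm",
    "normal_distance_mm",
]


def results_to_frame(results: Sequence[TargetingResult]) -> pd.DataFrame:
    if not results:
        raise GeometryError("no results to tabulate")
    rows = [
        {
            "attempt": r.attempt,
            "entry_x_mm": r.planned_entry.x,
            "entry_y_mm": r.planned_entry.y,
            "entry_z_mm": r.planned_entry.z,
            "target_x_mm": r.planned_target.x,
            "target_y_mm": r.planned_target.y,
            "target_z_mm": r.planned_target.z,
            "normal_distance_mm": r.normal_distance_mm,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_results_table(results: Sequence[TargetingResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.6f")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise GeometryError(f"results table missing columns: {sorted(missing)}")
    return df


def summary_from_table(df: pd.DataFrame) -> AccuracySummary:
    return summarize([float(d) for d in df["normal_distance_mm"]])
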