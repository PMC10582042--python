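"""3D Slicer markups interop (.mrk.json and legacy .fcsv) plus plain CSV.

Internal convention is RAS; LPS files have their first two coordinates
sign-flipped at the I/O boundary, so sign errors cannot leak into the
geometry.  Legacy .fcsv files without a ``# CoordinateSystem`` header
default to LPS with a logged warning, matching the common dialect.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .geometry import Point3

__all__ = [
    "MarkupsDocument",
    "MarkupsError",
    "read_markups",
    "write_markups",
    "read_points_csv",
    "write_points_csv",
]

log = logging.getLogger("arthroguide.markups")

INTERNAL_FRAME = "scanner-RAS"


class MarkupsError(ValueError):
    pass


def _to_ras(x: float, y: float, z: float, system: str) -> tuple[float, float, float]:
    if system == "RAS":
        return x, y, z
    if system == "LPS":
        return -x, -y, z
    raise MarkupsError(f"unknown coordinate system {system!r}")


@dataclass(frozen=True)
class MarkupsDocument:
    """Labelled control points in the internal RAS frame."""

    points: tuple[Point3, ...]
    dialect: str  # "mrk.json" | "fcsv" | "csv"
    coordinate_system: str  # as declared in the source file

    def __post_init__(self) -> None:
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise MarkupsError(f"duplicate labels in document: {dupes}")

    def get(self, label: str) -> Point3:
        for p in self.points:
            if p.label == label:
                return p
        raise MarkupsError(f"no control point labelled {label!r}")

    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.points)


def _read_mrk_json(path: Path) -> MarkupsDocument:
    data = json.loads(path.read_text())
    try:
        markups = data["markups"]
    except (KeyError, TypeError) as exc:
        raise MarkupsError(f"{path}: not a Slicer markups JSON file") from exc
    points = []
    system = "LPS"
    for m in markups:
        system = m.get("coordinateSystem")
        if system is None:
            log.warning("%s: no coordinateSystem declared, assuming LPS", path)
            system = "LPS"
        for cp in m.get("controlPoints", []):
            x, y, z = (float(v) for v in cp["position"])
            rx, ry, rz = _to_ras(x, y, z, system)
            points.append(
                Point3(rx, ry, rz, frame=INTERNAL_FRAME, label=str(cp.get("label", "")))
            )
    return MarkupsDocument(points=tuple(points), dialect="mrk.json",
                           coordinate_system=system)


def _read_fcsv(path: Path) -> MarkupsDocument:
    system = None
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "CoordinateSystem" in line:
                token = line.split("=")[-1].strip()
                system = {"0": "RAS", "1": "LPS", "RAS": "RAS", "LPS": "LPS"}.get(token)
                if system is None:
                    raise MarkupsError(f"{path}: unknown CoordinateSystem {token!r}")
            continue
        rows.append(line.split(","))
    if system is None:
        log.warning("%s: no CoordinateSystem header, defaulting to LPS", path)
        system = "LPS"
    points = []
    for row in rows:
        if len(row) < 12:
            raise MarkupsError(f"{path}: malformed fcsv row {row!r}")
        x, y, z = float(row[1]), float(row[2]), float(row[3])
        label = row[11]
        rx, ry, rz = _to_ras(x, y, z, system)
        points.append(Point3(rx, ry, rz, frame=INTERNAL_FRAME, label=label))
    return MarkupsDocument(points=tuple(points), dialect="fcsv",
                           coordinate_system=system)


def read_markups(path: str | Path) -> MarkupsDocument:
    """Read a markups file, converting declared LPS/RAS to internal RAS."""
    path = Path(path)
    if not path.exists():
        raise MarkupsError(f"no such file: {path}")
    name = path.name.lower()
    if name.endswith(".mrk.json") or name.endswith(".json"):
        return _read_mrk_json(path)
    if name.endswith(".fcsv"):
        return _read_fcsv(path)
    if name.endswith(".csv"):
        return read_points_csv(path)
    raise MarkupsError(f"unknown markups dialect for {path.name!r}")


def write_markups(
    doc_or_points: MarkupsDocument | Iterable[Point3],
    path: str | Path,
    coordinate_system: str = "LPS",
) -> None:
    """Write control points as .mrk.json or .fcsv in the declared system."""
    points = (
        doc_or_points.points
        if isinstance(doc_or_points, MarkupsDocument)
        else tuple(doc_or_points)
    )
    path = Path(path)
    name = path.name.lower()
    out = []
    for p in points:
        # Internal is RAS; the LPS<->RAS flip is an involution.
        x, y, z = _to_ras(p.x, p.y, p.z, coordinate_system)
        out.append((p.label, x, y, z))
    if name.endswith(".mrk.json") or name.endswith(".json"):
        doc = {
            "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json",
            "markups": [
                {
                    "type": "Fiducial",
                    "coordinateSystem": coordinate_system,
                    "controlPoints": [
                        {"id": str(i + 1), "label": label, "position": [x, y, z]}
                        for i, (label, x, y, z) in enumerate(out)
                    ],
                }
            ],
        }
        path.write_text(json.dumps(doc, indent=2))
    elif name.endswith(".fcsv"):
        lines = [
            "# Markups fiducial file version = 4.11",
            f"# CoordinateSystem = {coordinate_system}",
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
        ]
        for i, (label, x, y, z) in enumerate(out):
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{x:.6f},{y:.6f},{z:.6f},"
                f"0,0,0,1,1,1,0,{label},,"
            )
        path.write_text("\n".join(lines) + "\n")
    else:
        raise MarkupsError(f"unknown markups dialect for {path.name!r}")


def read_points_csv(path: str | Path) -> MarkupsDocument:
    """Plain CSV with columns label,x,y,z taken to be in the internal frame."""
    path = Path(path)
    points = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"label", "x", "y", "z"} <= set(
            reader.fieldnames
        ):
            raise MarkupsError(f"{path}: CSV must have columns label,x,y,z")
        for row in reader:
            points.append(
                Point3(
                    float(row["x"]), float(row["y"]), float(row["z"]),
                    frame=INTERNAL_FRAME, label=row["label"],
                )
            )
    return MarkupsDocument(points=tuple(points), dialect="csv",
                           coordinate_system="RAS")


def write_points_csv(points: Iterable[Point3], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z"])
        for p in points:
            writer.writerow([p.label, f"{p.x:.6f}", f"{p.y:.6f}", f"{p.z:.6f}"])
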