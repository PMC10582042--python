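"""Reference datasets distributed with the toolkit.

The cadaver shoulder study: five planned entry/target pairs in scanner
millimetre coordinates and the measured normal target-to-needle distance of
each attempt.  The scanner's RAS/LPS orientation was not recorded with the
coordinates, so they are kept in an opaque ``"scanner"`` frame; all
quantities derived from them (trajectory lengths, angles between planned
paths, summary statistics of the printed distances) are invariant to that
choice.  The per-attempt distances cannot be recomputed from this table —
the artifact points picked on the confirmation images were not preserved —
so the distances are data, not derived values.

A prior flat gel-phantom evaluation of the same toolkit reached
2.2 ± 0.7 mm; the clinical requirement for arthrography targeting is 5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import Point3

__all__ = ["StudyAttempt", "shoulder_cadaver_study", "CLINICAL_ACCURACY_BOUND_MM"]

#: Clinically required targeting accuracy for arthrography, millimetres.
CLINICAL_ACCURACY_BOUND_MM = 5.0

#: Phantom-study comparison figures (mean, sample SD), millimetres.
PHANTOM_STUDY_MM = (2.2, 0.7)

_SCANNER = "scanner"

_STUDY = (
    ("T1", (-73.27, -9.66, 38.39), (-75.82, -46.77, 38.09), 4.8),
    ("T2", (-76.34, -9.19, 34.79), (-76.34, -47.01, 34.79), 2.44),
    ("T3", (-74.48, -9.45, 18.59), (-77.39, -45.62, 18.59), 3.70),
    ("T4", (-68.57, -8.20, 34.73), (-76.56, -45.20, 34.79), 2.67),
    ("T5", (-79.76, -8.86, 32.09), (-76.98, -48.53, 32.09), 2.50),
)


@dataclass(frozen=True)
class StudyAttempt:
    label: str
    entry: Point3
    target: Point3
    normal_distance_mm: float


def shoulder_cadaver_study() -> tuple[StudyAttempt, ...]:
    """The five shoulder-targeting attempts of the cadaver evaluation."""
    return tuple(
        StudyAttempt(
            label=label,
            entry=Point3(*e, frame=_SCANNER, label=f"{label}-entry"),
            target=Point3(*t, frame=_SCANNER, label=f"{label}-target"),
            normal_distance_mm=d,
        )
        for label, e, t, d in _STUDY
    )
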