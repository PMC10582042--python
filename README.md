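# arthroguide

Computational toolkit for MRI-only arthrography needle guidance: planning
needle angulation from MR-selected entry/target points, checking it against
a hand-held guide's tilt range, evaluating targeting accuracy from
confirmation images, and generating the spatially-unique grid-template
patterns that let a small imaged patch identify its own position on the
skin. Written for interventional-MRI researchers and engineers building or
evaluating grid-plus-guide workflows that replace fluoroscopic needle
placement (and its ionizing radiation) with a single MRI session.

## What it computes

**Planning.** With the spherical origin at the target, the entry point sits
at `(r, θ, φ)` relative to the guide's home axis:

```
r⃗ = R_z(φ) R_y(θ) (0, 0, r)ᵀ = (r cosφ sinθ, r sinφ sinθ, r cosθ)ᵀ
```

so `θ = arccos(r_z/r)`, `φ = atan2(r_y, r_x)`. The guide's bubble level
reads the tilt as `pitch = atan(tanθ·cosφ)`, `yaw = atan(tanθ·sinφ)`,
feasible when both are within the device half-range (±6° studied, ±35°
planned).

**Evaluation.** Points picked along the needle's image artifact get a total
least-squares 3D line fit (principal right-singular vector of the centred
point matrix); the attempt's error is the perpendicular distance
`‖(p − anchor) × direction‖` from the planned target `p` to that line, and
a study summarises as mean ± sample SD.

**Grid templates.** Patterns over a small symbol alphabet in which every
`k × k` window occurs at most once (enforced and exhaustively verified), so
`localize` maps an observed window to its unique grid position — with a
Hamming mismatch budget for corrupted observations when the pattern was
generated with guaranteed inter-window separation.

**Synthetic data.** Seed-deterministic generators for needle observations
with planted lateral offsets, whole studies with an additive error budget
(template slip, tilt quantization, depth error), and voxelized NIfTI
renderings of patterned slabs — so every stage is testable without scanner
data.

## Worked example

The package ships the five-attempt cadaver shoulder dataset
(`arthroguide.datasets.shoulder_cadaver_study`). Summarising its measured
normal target-to-needle distances:

```python
>>> from arthroguide import summarize
>>> from arthroguide.datasets import shoulder_cadaver_study
>>> study = shoulder_cadaver_study()
>>> summarize([a.normal_distance_mm for a in study])
AccuracySummary(n=5, mean_mm=3.222, sd_mm=1.0193233049430392)
```

i.e. 3.2 ± 1.0 mm at one decimal — under the 5 mm accuracy required
clinically. Planning the fourth attempt against the studied guide (home
axis +y, pointing outward from the joint through the skin):

```
$ arthroguide plan --entry entries.mrk.json:T4 --target targets.mrk.json:T4 \
      --home-axis 0,1,0 --limit 6
{
  "label": "T4",
  "theta_deg": 12.186007463454605,
  "phi_deg": 0.43024807932069536,
  "r_mm": 37.85292194798177,
  "pitch_deg": 12.185674155493539,
  "yaw_deg": 0.09291199344392521,
  "limit_deg": 6.0,
  "feasible": false
}
```

The 12.2° tilt exceeds the ±6° device (exit code 2) but would fit the
planned ±35° revision — the geometric face of the observation that a 6°
range restricts the selectable entry zone. Attempt T2 runs straight along
the home axis (`theta_deg: 0.0, r_mm: 37.82, feasible: true`).

Other subcommands: `evaluate` (artifact points → normal distance),
`summarize`, `grid-gen` / `grid-locate`, `simulate needle|study|volume`,
and `run` for the full plan → confirm → evaluate workflow with a
reproducibility manifest. The same functionality is available as a library
(`arthroguide.geometry`, `.evaluation`, `.grid`, `.synthetic`,
`.markups`/`.tables`/`.workflow`).

See `docs/methods.md` for conventions, tie-breaks, the error-budget model,
and known limitations.

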