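# Methods

## The procedure being modelled

In MRI-only arthrography with a grid template and hand-held guide, a
radiologist picks an entry point on a flexible, MRI-visible silicone grid
conformed to the skin and a target point inside the joint, both on MR images
in scanner millimetre coordinates. The guide holds the needle along a fixed
"home" direction and is tilted until its spherical bubble level shows the
planned pitch and yaw; the needle is then advanced to the planned depth.
Accuracy is verified on confirmation images: points are picked along the
needle's image artifact, a 3D line is fitted to them, and the error is the
perpendicular distance from the planned target to that line.

This package implements the computation around that workflow: angulation
planning, guide-range feasibility, line-fit evaluation, generation and
localization of spatially-unique grid patterns, and synthetic data for
testing every stage without a scanner.

## Planning geometry

With the spherical origin at the target, the entry sits at `(r, θ, φ)`:
`r` is the entry–target distance, `θ ∈ [0°, 180°]` the angle from the
guide's home axis, `φ ∈ (−180°, 180°]` the azimuth. The forward map is

    r⃗ = R_z(φ) R_y(θ) (0, 0, r)ᵀ
       = (r cosφ sinθ, r sinφ sinθ, r cosθ)ᵀ

with the standard rotation matrices about z and y. `R_y` here is the
standard y-axis rotation; it is the unique choice consistent with the
component formulas above (a y-rotation written in the same layout as a
z-rotation does not reproduce them). The inverse map is
`θ = arccos(r_z/r)`, `φ = atan2(r_y, r_x)`.

Numerical choices and tie-breaks:

* On the poles (`sinθ = 0`) the azimuth is undefined; we fix `φ := 0` so
  that the home position maps deterministically to zero readings.
* Angles are degrees at every public interface, radians internally.
* `FrameConvention` carries the guide's home axis *and* an azimuth-zero
  axis, both in scanner coordinates. The home axis points from the target
  toward the entry (outward through the skin). The azimuth axis is needed
  because `φ` is only defined relative to some reference perpendicular to
  the home axis; carrying it explicitly makes the angles exactly invariant
  under a common rigid transform of points and convention, which is also a
  tested property. When omitted it is completed deterministically from the
  scanner x axis (or y, if the home axis is within 1e−9 of x).
* The scanner-to-guide relation during any given procedure is configuration,
  not something the planning math can infer: the reference dataset's
  coordinates alone cannot disambiguate it, so `home_axis` is an explicit
  parameter with default `(0, 0, 1)`.

### Guide readings

The bubble level reads two tilts about orthogonal horizontal axes. We use
the projection decomposition

    pitch = atan(tanθ · cosφ),   yaw = atan(tanθ · sinφ),

evaluated as `atan2(sinθ·cosφ, cosθ)` (and similarly for yaw) so that
`θ ≥ 90°` produces a finite, necessarily out-of-range reading instead of a
tangent singularity. Sequential Euler decompositions differ from this
projection convention only in second order, well under a tenth of a degree
inside the ±6° device range and noticeable only above ~10°; within the
planned ±35° range the difference remains below the device's own reading
resolution. Feasibility is `|pitch| ≤ L` and `|yaw| ≤ L` with the
half-range `L` defaulting to 6° (studied device) and configurable (35° for
the planned revision); the report includes the signed margin per axis.

## Targeting-error evaluation

`fit_line` performs a total-least-squares 3D line fit: the direction is the
principal right-singular vector of the centred point matrix, which minimises
the sum of squared *perpendicular* residuals over all lines — the
appropriate criterion when no axis is a privileged "independent" variable.
The fit is tested against an independent brute-force oracle (direction grid
at 2° steps through the centroid) on every small instance.

* Sign/tie-breaks: the direction's largest-magnitude component is made
  positive; if the top two singular values tie to within 1e−9 relative
  (an isotropic cloud), the fit is flagged `degenerate` and the direction
  among the tied singular vectors with lexicographically largest absolute
  components is chosen, so the output is deterministic across SVD
  implementations.
* Fewer than 2 points, or all points coincident, is an error.

The per-attempt error is the perpendicular point-to-line distance
`‖(p − anchor) × direction‖`, one value per attempt (the study reports a
single normal distance per target, not an average over artifact points).
The study summary is the arithmetic mean and the *sample* (n−1) standard
deviation: on the reference dataset's distances (4.8, 2.44, 3.70, 2.67,
2.50 mm) the sample SD is 1.019 → 1.0 at one decimal, whereas the
population SD (0.912 → 0.9) is inconsistent with the reported ±1.0, which
pins down the convention. Distances are kept at full precision and rounded
only when formatting reports.

The five per-attempt distances in the reference dataset are measured data:
the artifact points behind them were not preserved, so only the summary
statistics — not the individual rows — are recomputable.

## Spatially-unique grid patterns

The template's defining property, abstracted: a `rows × cols` array of
symbols from an alphabet of size `A` in which every `k × k` contiguous
window occurs at most once, so an imaged patch of `k × k` cells identifies
its global position. A pattern with `W = (rows−k+1)(cols−k+1)` windows can
only exist when `W ≤ A^(k²)`; this counting bound is enforced up front.
Note it rules out, e.g., a 32×32 binary pattern with k = 3 (900 windows,
512 possibilities) — such requests fail fast rather than search forever.

Construction is a seeded randomized row-major fill with chronological
backtracking: the cell at `(r, c)` with `r, c ≥ k−1` completes exactly one
window, which must be new (and, optionally, at Hamming distance
`≥ min_hamming` from every previous window). Symbol order per cell is a
seeded shuffle, so generation is deterministic per seed; exhausting the node
budget restarts with fresh shuffles, and exhausting restarts raises — a
non-unique pattern is never returned silently. Uniqueness is additionally
re-verified by exhaustive window enumeration before returning. Perfect-map
(de Bruijn torus) constructions achieve the counting bound exactly but are
unnecessary at template scale, where `W` is far below it.

Localization is exhaustive Hamming matching over all windows: exact
(`localize`, unique by the invariant) or with a mismatch budget `m`
(`localize_noisy`, all candidates sorted by distance then row-major).
Unambiguous recovery under `m` corrupted cells is guaranteed only when
`2m <` the pattern's minimum pairwise window Hamming distance, which
`min_window_hamming` computes; unconstrained random patterns typically have
minimum distance 1, so noise tolerance must be designed in via
`min_hamming` at generation time. That is a code-design constraint — a
binary `k = 3` pattern admits at most 40 windows at distance 3 — so
separated patterns generally need a larger alphabet (the tests use
12×12, `A = 4`, distance ≥ 3).

Window orientation is assumed known: the template has a fixed orientation
on the patient, so no rotation/reflection search is performed. The cell
pitch defaults to 5 mm and is configurable; it only scales index → mm
conversion.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes, not
MR physics.

* **Needle observations** (`simulate_needle_points`): `n` points (default a
  uniform draw in [10, 20], matching manual artifact picking) spaced
  uniformly along the needle from the skin to 15% beyond the target depth,
  on a line displaced from the planned trajectory by exactly `offset_mm` in
  a seeded random perpendicular azimuth, plus isotropic Gaussian picking
  jitter `σ` per point. The planted offset is therefore the ground-truth
  normal distance: with `σ = 0` the pipeline recovers it to 1e−9 mm, and
  with jitter to Monte-Carlo tolerance.
* **Study simulation** (`simulate_targeting_study`): independent additive
  error knobs named after the observed failure modes — 2D isotropic
  template slip (σ, mm) in the plane perpendicular to the trajectory,
  which alone makes the error Rayleigh-distributed with mean `σ√(π/2)`;
  quantization of the guide's tilt reading (step, degrees), applied to the
  polar tilt θ only so the worst-case miss is `depth·tan(step/2)`
  (quantizing pitch and yaw independently would inflate that bound by √2
  and break the clean closed-form check); and depth error (σ, mm) along
  the needle axis, which moves the tip but not the needle *line* and hence
  leaves this study's line-distance metric unchanged — a deliberate
  illustration of what the metric does and does not see. No quantitative
  deformation data exists for the template, so the default σ values are
  illustrative, not calibrated; passing tests validate the pipeline's
  mathematics, not clinical error magnitudes.
* **Grid volumes** (`render_grid_volume`): a voxelized slab carrying the
  pattern as linear symbol → intensity modulation, flat or wrapped on a
  cylinder (axis along x), plus optional Gaussian intensity noise; written
  as NIfTI with an isotropic voxel affine. A noise-free flat rendering
  resampled at cell centres reproduces the symbol array exactly; voxels
  larger than the cell pitch make the pattern unresolvable and are
  rejected. There is no tissue, needle mechanics, or MR contrast model.

Everything is seed-deterministic: identical spec + seed gives bit-identical
output.

## I/O and workflow

Internal coordinates are RAS; 3D Slicer markups files (`.mrk.json`,
`.fcsv`) are converted at the boundary using the file's declared coordinate
system (LPS flips the sign of x and y). Legacy `.fcsv` files without a
`# CoordinateSystem` header default to LPS with a logged warning. Plain
CSV point lists (`label,x,y,z`) are taken as already internal. Results
tables carry one row per attempt (entry, target, normal distance, full
precision, formatted at 1e−6 mm). `run_workflow` chains plan → feasibility
→ (simulated) confirmation → evaluation and writes a reproducibility
manifest (config, seed, versions) with every run.

## Problem sizes and tolerances

Test and acceptance runs use: 1000 seeded samples for rotation/round-trip
identities (tolerances 1e−9 mm and 1e−6 degrees); 200 seeds × 15 points for
offset-recovery Monte Carlo (mean within 0.1–0.15 mm of the planted
offset); 500 attempts for the Rayleigh check (within 10% of `σ√(π/2)`);
16×16 binary and 32×32 ternary patterns (k = 3) for exhaustive
uniqueness/localization; and a 12×12, alphabet-4, distance-3 pattern for
noisy localization. These sizes give stable statistics in seconds while
keeping every check exhaustive where exhaustiveness is the point.

## Known limitations

* The pitch/yaw decomposition is one convention among several; it matters
  only beyond ~10° of tilt and is documented rather than configurable.
* Pattern localization does not search over rotations/reflections of the
  window; a rotated template on the patient would need that extension.
* The silicone template's deformation (the dominant error source on curved
  anatomy) is modelled only as stochastic slip, not mechanically.
* No DICOM ingestion, no image segmentation of the needle artifact: the
  toolkit consumes point lists, as in the manual procedure.
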