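# Methods

## Scope and data model

`contourdose` evaluates how an automatically produced set of radiotherapy
structure delineations differs from a manual reference, geometrically and
dosimetrically, and whether the differences are clinically acceptable. It
does not segment images and does not compute dose: dose grids and
delineations are inputs (DICOM-RT, NIfTI, or JSON planar contours), or are
synthesized by the phantom module.

All geometry lives in patient millimetres, right-handed, with voxel-center
addressing and 0-based indices; arrays are indexed `(i, j, k)` for
`(x, y, z)` and slices are indexed by z. Voxel volume is
`dx·dy·dz / 1000` cc everywhere. Structures are boolean voxel masks
(voxel-count volumes, no partial-volume weighting); planar contours are
rasterized with the even-odd rule on voxel centers, so holes and multiply
connected slices (lungs, heart) work without special cases. Dose may be
trilinearly resampled onto a structure grid; masks are never resampled —
contours are rasterized directly on the evaluation grid, avoiding mask
interpolation artefacts.

## Geometric agreement

DSC(A, B) = 2|A∩B|/(|A|+|B|) in voxel counts (0 = no overlap,
1 = complete overlap). The surface of a mask is the set of centers of its
boundary voxels (a true voxel with at least one of its 6 face neighbors
false or outside the grid). MDA is the mean Euclidean distance, in 3D and
with anisotropic spacing, from each surface point of the automatic
structure to the nearest surface point of the manual one (directed,
automatic → manual, the default); the symmetric mode averages the two
directed values. Both conventions exist in the field, so the mode is
recorded in every result. Distances use a KD-tree over exact surface-point
sets; tests verify agreement with an all-pairs brute-force oracle to 1e-9
relative.

## DVH metrics

The cumulative DVH samples, at uniform dose-bin edges (default 0.05 Gy),
the percentage of structure voxels with dose ≥ the edge. Dx% inverts that
curve — the largest dose received by at least x% of the volume — with
linear interpolation between edges; the result is clamped to the
structure's actual [min, max] dose. The clamp matters at plateaus: a pure
piecewise-linear inversion overshoots by up to one bin where the curve is
flat, which would give a uniform dose a small positive homogeneity index
instead of exactly 0 and would make D100% land one bin below the true
minimum. With the clamp the degenerate limits are exact, and everywhere
else the value stays within one bin of the voxel-sort definition (tested,
including that finer bins shrink the discrepancy). Vx interpolates the
forward curve at x Gy and uses the ≥-threshold convention so V0 = 100%
exactly; on interpolated curves "more than" and "at least" coincide.

CI = TVPTV²/(TV·PTV) with TV the volume receiving at least the
prescription, PTV the target volume, TVPTV their overlap (all in cc on the
shared grid); an empty prescription isodose returns CI = 0 with a warning
rather than an error. HI = (D2% − D98%)/D50% (ICRU 83), undefined when
D50% = 0.

## Paired comparison

For each (structure, metric), per-case manual and automatic values are
paired by case ID and compared with a two-sided paired t-test:
t = mean(d)/(sd(d)/√n) on the differences d, sd with the n−1 denominator,
n−1 degrees of freedom. Zero-variance differences are degenerate: P = 1 is
reported, with t = 0 for identical pairs and t = NaN for an exactly
constant nonzero shift (no sampling variability to test against).
Normality of the differences is assumed and not gated automatically — the
flags mean what a routine paired t-test means. No multiple-testing
correction is applied by default, matching common practice in delineation
studies that report ~20 metrics side by side; Holm adjustment is available
by flag. Means/SDs are rounded half-away-from-zero to two decimals for
display only; all statistics use unrounded values.

The clinical acceptability criterion is strict: Δ = |manual mean −
automatic mean| < 1 Gy for dose metrics, < 1 percentage point for volume
metrics, applied to the difference of means (not per-case maxima).
`max_abs_difference` locates the worst metric under a unit or metric-name
filter, breaking Δ ties by structure then metric name.

## Phantom

The phantom emulates a thoracic evaluation setting at desk scale:

- **Grid**: 64×64×40 voxels at 4×4×5 mm (a scaled-down 512×512 / 5 mm CT
  geometry; full resolution is configurable but unnecessary for the
  statistics the phantom serves).
- **Anatomy**: lung ellipsoids (semi-axes 30×70×80 mm at x = ±48 mm),
  a heart ellipsoid, a spinal-cord cylinder (radius 6 mm) running the full
  z extent, its PRV (cord dilated by 5 mm — the margin is a configurable
  stand-in, as clinical PRV margins vary), and a tubular esophageal target
  (radius 9 mm, length 170 mm) anterior to the cord. Bilateral lung is the
  union of the two lungs. Per-case anatomy jitters organ scale (SD 3%) and
  position (SD 2 mm) so between-case variability exists.
- **Dose**: prescription (60 Gy) inside the target, falling off as
  exp(−d/λ) with d the Euclidean distance to the target and λ = 15 mm.
  This is an idealized conformal field, not a dose calculation: it gives
  the metric code a plausible spatial dose with a steep gradient at the
  cord/target interface — the regime where contour differences matter most
  — and is exactly monotone in distance, which the tests exploit. Optional
  smooth dose noise is off by default.
- **Automatic contours**: the manual mask's signed distance field is
  sampled under a small rigid shift (0.4 × amplitude, random direction)
  and thresholded against a smooth band-limited Gaussian radial field
  (correlation length 40 mm) scaled to a per-structure amplitude in mm.
  One amplitude knob per primitive structure controls the disagreement;
  `calibrate_perturbation` bisects it until the mean DSC over a seeded
  case set lands in a requested band (mean DSC is monotone in the
  amplitude). The shipped default amplitudes (lungs 2.625 mm, heart
  3.0 mm, cord 2.625 mm) were fixed by running that calibration against
  per-structure DSC bands of roughly 0.97 / 0.93 / 0.84 — values typical
  of published thoracic auto-segmentation results — over 10 cases.
- **Determinism**: every draw derives from
  `(master seed, case index, structure stream)`, so cohorts are
  reproducible bit-for-bit; a written cohort carries a manifest with the
  per-case seed material and a configuration digest.

What the phantom does **not** emulate: CT intensities, inter-observer
ambiguity in what the "true" contour is, organ-specific perturbation
anisotropy (real automatic contours fail at specific anatomic interfaces,
e.g. the lung hilum), and separately optimized plans per delineation set —
one dose field per case is evaluated on both structure sets. Passing tests
therefore show the *evaluation machinery* is correct and well calibrated,
not that any particular segmentation model is clinically safe.

## Numerical choices and edge cases

- DVH bin width 0.05 Gy by default: finer than the two-decimal reporting
  precision while cheap at desk scale.
- Contour rasterization closes polygons explicitly; z coordinates must hit
  a grid slice within half a slice thickness, else an out-of-extent error.
- Dose resampling outside the source voxel-center hull yields 0 Gy with a
  logged warning.
- Margin expansion uses a Euclidean distance transform with anisotropic
  sampling; note that dilating by a then b on the voxel lattice is a
  (strict) subset of dilating by a+b, because chained digital dilations
  must pass through voxel centers — the continuum equality does not hold
  exactly and is not asserted.
- DSC of two empty masks, metrics of an empty structure, and HI at
  D50% = 0 raise typed errors rather than returning sentinels.
- Both empty-intersection and exact-overlap limits (DSC 0/1, MDA 0,
  HI 0, CI 1) are exact, not approximate.

## Problem sizes used in tests

Oracle-equivalence tests run 50 random phantoms on grids up to ~15³ voxels
(brute-force all-pairs oracles are exhaustive there); calibration and
cohort tests use the default 64×64×40 grid with 10 or fewer cases; the
statistical calibration uses 1000 replicate cohorts of 19 cases at the
metric level. These sizes make the full suite run in about two minutes on
one CPU while keeping every check exhaustive where exhaustiveness is the
point.
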