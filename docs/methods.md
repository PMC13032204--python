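# Methods

## Tissue model

Single-slice body composition at L3 treats per-pixel Hounsfield units as a
tissue signature: adipose tissue occupies −190…−30 HU and skeletal muscle
−29…+150 HU (both windows inclusive). HU are rounded to the nearest integer
before comparison, because CT HU are natively integer and the two printed
integer windows then partition the fat/muscle axis exhaustively — without
rounding, a real-valued HU of −29.6 would fall between the windows.
Thresholds are configurable through `HURanges`; the invariant
`fat_lo ≤ fat_hi < muscle_lo ≤ muscle_hi` keeps the candidates disjoint.

Thresholds alone cannot distinguish SAT from VAT (both are fat) or wall
muscle from visceral organs (bowel and solid organs also sit in the muscle
window). The spatial model is therefore:

1. **Body mask** — threshold at `body_threshold_hu` (−500 HU, midway between
   air and fat), morphological closing, keep the largest connected
   component (this drops the scanner table; ties broken by first raster-scan
   pixel), fill holes. Hole filling uses 4-connectivity for the background
   complement while components use 8-connectivity, the standard pairing that
   avoids topological paradoxes.
2. **Muscle wall** — close the muscle-range candidates inside the body with
   a disk of radius `closing_radius_px` (default 3 px; seals anatomical gaps
   up to ≈ 2× the radius), drop components below `min_component_px`
   (default 10 px). Of the resulting components, only those **adjacent to
   the boundary-connected region** are kept as wall: muscle-range tissue in
   the interior (organs) is not wall. Without this adjacency rule every
   organ would be absorbed into the "muscle" class; with it, interior
   muscle-range pixels fall into the visceral compartment and are labelled
   OTHER, which is the behaviour the per-pixel contract requires.
3. **Compartments** — the subcutaneous region is every component of
   body ∖ wall touching the body surface; the visceral region is the
   remainder. The three regions partition the body by construction.
4. **Labels** — SAT/VAT/IMAT are the fat candidates intersected with the
   subcutaneous region, visceral region and wall respectively; MUSCLE is
   muscle-range ∩ wall; everything else in the body (bone > +150 HU, bowel
   gas, organs) is OTHER. A `merge_imat_into_muscle` switch supports the
   sensitivity analysis of counting intramuscular fat with muscle, since
   conventions differ on whether "muscle area" includes IMAT; the default
   reports IMAT separately.

Areas are exact arithmetic on pixel counts:
`area_cm2 = count × spacing_row_mm × spacing_col_mm / 100`. For anisotropic
pixels the product of the two spacings is the only reading of "pixel spacing"
that yields an area; it reduces to spacing² for the square pixels typical of
abdominal CT.

A known limitation of the compartment rule: if visceral organs touch the
inner surface of the muscle wall with no intervening fat plane, wall and
organ merge into one muscle-range component and the organ is misclassified
as muscle. In real anatomy the retroperitoneal/preperitoneal fat plane
usually provides that separation; the separability condition is a fat gap
wider than twice the closing radius (≈ 4.8 mm at default settings and
0.8 mm pixels).

## Agreement statistics

* **Dice**: 2|A∩B|/(|A|+|B|) per tissue. Two empty masks score 1.0
  (agreement on absence); the number of both-empty cases is reported so they
  can be excluded if desired.
* **ICC**: computed from the ANOVA mean squares of the subjects × raters
  table. The default form is ICC(A,1) — two-way, absolute agreement, single
  measures — `(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))`, the
  conventional model for method comparison of single measurements because it
  penalises systematic offsets; consistency ICC(C,1) and one-way ICC(1) are
  available behind a flag. Confidence intervals use the F-based method with
  Satterthwaite degrees of freedom for the absolute-agreement form (verified
  against pingouin in the tests). All-identical tables degenerate to an
  estimate of 1.0 with interval [1, 1] and a warning.
* **Pearson** r with t-based two-sided p (scipy).
* **Bland–Altman**: differences are automated − manual; bias = mean
  difference; limits of agreement = bias ± 1.96·SD with the sample (n−1) SD.
  The 1.96 multiplier is exposed as a parameter. A proportional-bias slope
  (regression of differences on pair means) is reported as an extension for
  detecting magnitude-dependent disagreement.

## Phantom generator

The phantom is parametric-elliptical rather than atlas-based so that ground
truth is analytic, every test is deterministic, and the repository needs no
image downloads. Concentric elliptical shells form the subcutaneous fat
ring (default thickness 25 mm), the muscle wall (12 mm) and the visceral
cavity; a 6 mm visceral fat plane lines the inside of the wall (emulating
retroperitoneal fat, and guaranteeing wall/organ separability as above), a
circular vertebral body (+700 HU) exercises the bone → OTHER pathway,
overlapping random disks of fat give the visceral compartment irregular
boundaries, and small fat pockets on the wall centreline exercise IMAT.
Defaults (512 × 512 raster at 0.8 mm, 150 × 110 mm semi-axes, 30% visceral
fat) give a medium adult abdomen with SAT ≈ 180 cm², VAT ≈ 75 cm², muscle
≈ 75 cm². Nominal HU values (fat −100, muscle +50, soft tissue +30, air
−1000) sit several noise SDs inside their windows. Noise is additive white
Gaussian in HU (default σ = 5, a typical abdominal-CT noise magnitude);
correlated CT noise texture is out of scope as it would not change what the
threshold logic is exposed to. Labels are assigned before noise, so truth is
exact by construction and `truth_areas` recomputes bit-exactly from the
truth mask.

When `visceral_fat_fraction` is small the lining is thinned so total
visceral fat matches the requested fraction, and at 0 it is absent — a
zero-fraction phantom truly has zero VAT. Note that a thinned lining can
drop below the separability condition, in which case organ pixels merge into
the muscle class; the default fraction keeps the lining at full thickness.

What passing phantom tests do **not** show: robustness to partial-volume
boundaries (phantom boundaries are hard), HU calibration drift, metal or
beam-hardening artifacts, anatomical variants (hernias, open muscle walls),
or contrast-enhanced organs. The phantom validates the compartment logic
and the statistics, not clinical accuracy.

## Simulated rater and calibration

A human re-segmentation is emulated by resampling the label raster through a
smooth random displacement field: white noise smoothed with a Gaussian
(σ = 8 px), normalised to unit RMS per axis, scaled by
`boundary_jitter_px`, applied with nearest-neighbour sampling so the output
is always a valid partition. Zero jitter is the identity. An optional
`flip_fraction` relabels a fraction of boundary pixels to a neighbouring
class. Expected Dice against truth decreases monotonically with jitter, so
`calibrate_rater` can bisect the amplitude to reach a target mean Dice over
a fixed seed set (common random numbers keep the bisection stable); the
calibration contract is agreement within ±0.01 of the target, and
unreachable targets fail loudly with the bracketing values. In the
validation workflow the targets are the published inter-rater Dice levels
for trained human evaluators: 0.982 (SAT), 0.940 (muscle), 0.932 (VAT).

Because area is a weakly-biased functional of boundary jitter (displacements
push boundaries in and out symmetrically), simulated-rater areas scatter
tightly around truth; cohort ICCs for automated-vs-simulated-manual
comparison therefore come out higher (≈ 0.99) than published
automated-vs-human values — the synthetic design checks internal
consistency and the "excellent agreement for adipose tissue" ordering, not
the exact clinical ICC magnitudes, which depend on real inter-method error
structure that no boundary-jitter model reproduces.

## Cohorts and the validation design

`generate_cohort` scales semi-axes, shell thicknesses, vertebra radius and
visceral fat fraction by independent uniform factors in [1 − v, 1 + v]
(default v = 0.2, a free knob chosen to give realistic between-subject
spread; no distributional description of real cohorts is available to
estimate it from). `validate` runs the full design at n = 30 — large enough
for stable ICCs, small enough to finish in well under a minute — with
duplicate simulated-manual segmentations on ~11% of cases for the
intra-rater table, mirroring the usual practice of re-segmenting a ~10%
subsample.

## Numerical choices

* HU are clipped to [−1024, 4000] at read/generation time.
* `np.rint` (banker's rounding) rounds HU; ties at .5 are absent in real
  integer-HU data, and any fixed deterministic rule preserves the partition
  property.
* DICOM export stores `round(HU) + 1024` as 16-bit unsigned with slope 1 /
  intercept −1024 (common CT encoding); round-trips are exact up to integer
  quantisation. Reading applies slope/intercept regardless of photometric
  interpretation, since rescale fully defines HU.
* Bisection in `calibrate_rater` runs at most 40 iterations or until the
  bracket is below 1e−4 px; the per-seed displacement fields are cached so
  repeated evaluations cost only the resampling.
* Mask files round-trip losslessly as indexed PNG or NIfTI (uint8).
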