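# l3comp

Automated CT body-composition analysis on a single axial slice at the third
lumbar vertebra (L3), with the full agreement-validation battery used to
compare an automated segmentation against a manual reference.

The L3 cross-section is the standard single-slice proxy for whole-body
composition: the cross-sectional areas of skeletal muscle and of the
subcutaneous (SAT), visceral (VAT) and intramuscular (IMAT) adipose
compartments at this level track whole-body muscle and fat mass, and are used
clinically for sarcopenia, obesity and prognosis. Manual segmentation of
these compartments takes tens of minutes per scan; `l3comp` implements the
classical automated alternative — Hounsfield-unit thresholding plus
morphological compartmentalization — together with the statistics needed to
validate it against a human rater.

## What it computes

**Segmentation.** Pixels are classified by calibrated HU: adipose tissue in
the inclusive window −190…−30 HU, skeletal muscle in −29…+150 HU (HU are
rounded to integers first, so the two windows tile the axis with no gap).
Fat is then split by anatomical compartment: fat outside the abdominal muscle
wall is SAT, fat enclosed by it is VAT, fat inside the wall itself is IMAT.
The wall is recovered morphologically (closing of the muscle-range candidates,
boundary-connected-component analysis), bone and visceral organs fall into an
OTHER class, and air is BACKGROUND.

**Areas.** For each tissue,

```
area (cm²) = pixel count × spacing_row (mm) × spacing_col (mm) ÷ 100
```

with the pixel spacing taken from the DICOM metadata.

**Agreement.** For paired measurements (automated vs manual, or repeated
manual segmentations) the package computes the Dice overlap
2|A∩B|/(|A|+|B|), the intraclass correlation ICC(A,1) — two-way,
absolute-agreement, single measures, with F-based 95% confidence intervals —
Pearson's r, and Bland–Altman bias with ±1.96·SD limits of agreement
(differences are automated − manual, so a negative bias means the automated
method underestimates).

**Phantoms.** Because patient CT data cannot be redistributed, the package
ships a seeded parametric phantom: an elliptical abdomen with a subcutaneous
fat ring, closed muscle wall, visceral cavity with irregular fat deposits, a
vertebral body and CT noise — with labels and areas known analytically. A
calibrated rater simulator (smooth random boundary displacement tuned to a
target mean Dice) lets the entire automated-vs-manual validation design run
end to end on synthetic cohorts.

## Worked example

```python
import l3comp as lc

case = lc.generate_phantom(lc.PhantomSpec(seed=7))       # synthetic L3 slice
mask = lc.classify(case.ct)                              # automated segmentation
areas = lc.compute_areas(mask, case.ct.spacing_row_mm, case.ct.spacing_col_mm)
print({t: round(areas.area_cm2(t), 2) for t in ("SAT", "VAT", "IMAT", "MUSCLE")})
print("dice SAT =", round(lc.dice(mask, case.truth, "SAT"), 4))
```

prints

```
{'SAT': 184.55, 'VAT': 74.22, 'IMAT': 0.95, 'MUSCLE': 73.52}
dice SAT = 1.0
```

— the automated segmentation recovers the phantom's known compartment areas
(here 184.55 cm² of subcutaneous fat, 74.22 cm² of visceral fat, 73.52 cm² of
wall muscle) exactly on a noise-free-boundary phantom, with perfect spatial
overlap for SAT.

The same pipeline runs from the shell:

```
l3comp phantom  --n 30 --seed 7 --out cohort/        # synthetic DICOM cohort
l3comp segment  cohort/*.dcm --out seg/              # masks + area CSV
l3comp agree    --pairs pairs.csv --out report.json --plots plots/
l3comp validate --n 30 --seed 7 --out validation/    # end-to-end design
```

`validate` generates a cohort, segments it automatically, simulates a manual
rater calibrated to published inter-rater Dice levels (0.982 SAT, 0.940
muscle, 0.932 VAT), and writes the reproducibility, Dice and
method-agreement tables plus one Bland–Altman plot per tissue.

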