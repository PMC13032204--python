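"""Seeded synthetic L3-like CT phantoms with analytic ground truth.

The phantom emulates the structures that matter to threshold-based body
composition on an axial abdominal slice: an elliptical cross-section with a
subcutaneous fat ring, a closed abdominal muscle wall, a visceral cavity
holding soft tissue and irregular fat deposits, a fat plane lining the
inside of the wall (the retroperitoneal/preperitoneal fat that separates
wall muscle from viscera), small intramuscular fat pockets, a high-HU
vertebral body, and air outside — plus additive Gaussian HU noise.  Labels
and areas are known by construction, so segmentation and the whole
agreement-validation design can be exercised without patient data.

`simulate_rater` produces human-like re-segmentations by warping the label
raster with a smooth random displacement field; `calibrate_rater` finds the
displacement amplitude that hits a target mean Dice, so simulated raters can
be pinned to published inter-rater fidelity levels.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .ct_io import CTSlice, LabelMask, TISSUE_CODES, HU_MIN, HU_MAX
from .segment import AreaReport, HURanges, compute_areas

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "RaterPerturbSpec",
    "generate_phantom",
    "simulate_rater",
    "calibrate_rater",
    "generate_cohort",
    "write_phantom_dicom",
]

_SAT = TISSUE_CODES["SAT"]
_VAT = TISSUE_CODES["VAT"]
_IMAT = TISSUE_CODES["IMAT"]
_MUSCLE = TISSUE_CODES["MUSCLE"]
_OTHER = TISSUE_CODES["OTHER"]
_BG = TISSUE_CODES["BACKGROUND"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic L3 slice.

    Geometry is in millimetres; nominal HU values sit well inside their
    tissue windows so only boundary handling (not noise) is stressed at
    realistic noise levels.  ``visceral_fat_fraction`` is the target
    fraction of the visceral cavity (vertebra excluded) occupied by fat —
    at 0 the phantom has no visceral fat at all.
    """

    rows: int = 512
    cols: int = 512
    spacing_mm: float = 0.8
    semi_axis_row_mm: float = 110.0   # anterior–posterior half-extent
    semi_axis_col_mm: float = 150.0   # lateral half-extent
    sat_ring_mm: float = 25.0
    muscle_wall_mm: float = 12.0
    fat_lining_mm: float = 6.0        # visceral fat plane inside the wall
    visceral_fat_fraction: float = 0.30
    vertebra_radius_mm: float = 22.0
    n_imat_pockets: int = 12
    imat_pocket_radius_mm: float = 1.6
    hu_air: float = -1000.0
    hu_fat: float = -100.0
    hu_muscle: float = 50.0
    hu_soft: float = 30.0
    hu_bone: float = 700.0
    noise_sd_hu: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0 or self.spacing_mm <= 0:
            raise ValueError("raster size and spacing must be positive")
        half_row = self.rows * self.spacing_mm / 2
        half_col = self.cols * self.spacing_mm / 2
        if self.semi_axis_row_mm >= half_row - self.spacing_mm or \
                self.semi_axis_col_mm >= half_col - self.spacing_mm:
            raise ValueError(
                f"body semi-axes ({self.semi_axis_row_mm}, {self.semi_axis_col_mm}) mm "
                f"do not fit a {self.rows}×{self.cols} raster at {self.spacing_mm} mm"
            )
        shells = self.sat_ring_mm + self.muscle_wall_mm + self.fat_lining_mm
        if shells >= min(self.semi_axis_row_mm, self.semi_axis_col_mm):
            raise ValueError("shell thicknesses leave no visceral cavity")
        if not 0 <= self.visceral_fat_fraction <= 1:
            raise ValueError("visceral_fat_fraction must lie in [0, 1]")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        ranges = HURanges()
        if not ranges.fat_lo <= self.hu_fat <= ranges.fat_hi:
            warnings.warn(f"nominal fat HU {self.hu_fat} outside the fat window", stacklevel=2)
        if not ranges.muscle_lo <= self.hu_muscle <= ranges.muscle_hi:
            warnings.warn(f"nominal muscle HU {self.hu_muscle} outside the muscle window", stacklevel=2)


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic slice: calibrated CT, ground-truth labels and areas."""

    ct: CTSlice
    truth: LabelMask
    truth_areas: AreaReport
    spec: PhantomSpec


@dataclass(frozen=True)
class RaterPerturbSpec:
    """Controls of the simulated human rater.

    boundary_jitter_px — RMS amplitude of the smooth random displacement
    applied to the label raster (0 = perfect rater); flip_fraction —
    fraction of class-boundary pixels relabelled to a random neighbour's
    class.
    """

    boundary_jitter_px: float = 0.0
    flip_fraction: float = 0.0
    seed: int = 0
    smooth_sigma_px: float = 8.0

    def __post_init__(self) -> None:
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be >= 0")
        if not 0 <= self.flip_fraction < 1:
            raise ValueError("flip_fraction must lie in [0, 1)")


def _mm_grid(spec: PhantomSpec):
    y = (np.arange(spec.rows) - (spec.rows - 1) / 2) * spec.spacing_mm
    x = (np.arange(spec.cols) - (spec.cols - 1) / 2) * spec.spacing_mm
    return np.meshgrid(y, x, indexing="ij")


def _inside_ellipse(yy, xx, a_row, a_col, cy=0.0, cx=0.0):
    return ((yy - cy) / a_row) ** 2 + ((xx - cx) / a_col) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomCase:
    """Render one phantom: labels by construction, then HU = nominal + noise.

    Identical spec (including seed) → bit-identical output.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    yy, xx = _mm_grid(spec)

    b, a = spec.semi_axis_row_mm, spec.semi_axis_col_mm
    s, w = spec.sat_ring_mm, spec.muscle_wall_mm

    body = _inside_ellipse(yy, xx, b, a)
    sat_inner = _inside_ellipse(yy, xx, b - s, a - s)
    wall_inner = _inside_ellipse(yy, xx, b - s - w, a - s - w)

    # visceral fat lining; thinned when the target fat fraction is small,
    # absent when it is zero
    b_in, a_in = b - s - w, a - s - w
    region = wall_inner.copy()  # visceral cavity incl. lining

    # vertebral body, posterior of centre
    vert_cy = 0.55 * b_in
    vertebra = (yy - vert_cy) ** 2 + xx ** 2 <= spec.vertebra_radius_mm ** 2
    vertebra &= wall_inner
    n_region = int((region & ~vertebra).sum())

    lining_mm = spec.fat_lining_mm if spec.visceral_fat_fraction > 0 else 0.0
    if lining_mm > 0:
        lining = wall_inner & ~_inside_ellipse(yy, xx, b_in - lining_mm, a_in - lining_mm)
        lining &= ~vertebra
        if n_region and lining.sum() / n_region > spec.visceral_fat_fraction:
            lining_mm *= spec.visceral_fat_fraction * n_region / lining.sum()
            lining = wall_inner & ~_inside_ellipse(yy, xx, b_in - lining_mm, a_in - lining_mm)
            lining &= ~vertebra
    else:
        lining = np.zeros_like(body)

    vat = lining.copy()
    # irregular visceral fat: overlapping random disks inside the cavity
    if spec.visceral_fat_fraction > 0 and n_region:
        b_c, a_c = b_in - lining_mm, a_in - lining_mm
        target = spec.visceral_fat_fraction * n_region
        for _ in range(2000):
            if vat.sum() >= target:
                break
            r = rng.uniform(3.0, 9.0)
            cy = rng.uniform(-b_c, b_c)
            cx = rng.uniform(-a_c, a_c)
            if not _inside_ellipse(np.array(cy), np.array(cx), max(b_c - r, 1e-6), max(a_c - r, 1e-6)):
                continue
            if np.hypot(cy - vert_cy, cx) <= spec.vertebra_radius_mm + r + 2.0:
                continue
            vat |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        vat &= region & ~vertebra

    # intramuscular fat pockets on the wall centreline
    imat = np.zeros_like(body)
    if spec.n_imat_pockets > 0 and spec.imat_pocket_radius_mm > 0:
        b_m, a_m = b - s - w / 2, a - s - w / 2
        thetas = rng.uniform(0, 2 * np.pi, size=spec.n_imat_pockets)
        for t in thetas:
            cy, cx = b_m * np.sin(t), a_m * np.cos(t)
            imat |= (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.imat_pocket_radius_mm ** 2
        imat &= sat_inner & ~wall_inner

    labels = np.full((spec.rows, spec.cols), _BG, dtype=np.uint8)
    labels[body] = _SAT                      # subcutaneous ring …
    labels[sat_inner] = _MUSCLE              # … then the wall …
    labels[wall_inner] = _OTHER              # … then cavity soft tissue
    labels[vat] = _VAT
    labels[imat] = _IMAT
    labels[vertebra] = _OTHER                # bone

    hu_by_label = np.array(
        [spec.hu_air, spec.hu_fat, spec.hu_fat, spec.hu_fat, spec.hu_muscle, spec.hu_soft]
    )
    hu = hu_by_label[labels]
    hu[vertebra] = spec.hu_bone
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)
    hu = np.clip(hu, HU_MIN, HU_MAX)

    truth = LabelMask(labels=labels)
    ct = CTSlice(
        hu=hu,
        spacing_row_mm=spec.spacing_mm,
        spacing_col_mm=spec.spacing_mm,
        source_id=f"phantom-{spec.seed}",
    )
    return PhantomCase(
        ct=ct,
        truth=truth,
        truth_areas=compute_areas(truth, spec.spacing_mm, spec.spacing_mm),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Simulated rater
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _unit_displacement(shape: tuple, seed: int, sigma: float):
    """Smooth random displacement field with unit RMS magnitude per axis."""
    rng = np.random.default_rng(seed)
    fields = []
    for _ in range(2):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        rms = np.sqrt((f ** 2).mean())
        fields.append(f / rms if rms > 0 else f)
    return tuple(fields)


def simulate_rater(truth: LabelMask, perturb: RaterPerturbSpec) -> LabelMask:
    """A human-like re-segmentation of ``truth``.

    The label raster is resampled through a smooth seeded random
    displacement field of RMS amplitude ``boundary_jitter_px`` (nearest-
    neighbour, so the result stays a valid partition), then a fraction of
    class-boundary pixels is flipped to a neighbouring class.  Zero jitter
    and zero flips return the input unchanged.
    """
    labels = truth.labels
    rows, cols = labels.shape
    out = labels

    if perturb.boundary_jitter_px > 0:
        dy, dx = _unit_displacement((rows, cols), perturb.seed, perturb.smooth_sigma_px)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        ri = np.clip(np.rint(rr + perturb.boundary_jitter_px * dy).astype(np.intp), 0, rows - 1)
        ci = np.clip(np.rint(cc + perturb.boundary_jitter_px * dx).astype(np.intp), 0, cols - 1)
        out = labels[ri, ci]

    if perturb.flip_fraction > 0:
        out = out.copy()
        rng = np.random.default_rng(perturb.seed + 1)
        boundary = np.zeros_like(out, dtype=bool)
        boundary[:-1, :] |= out[:-1, :] != out[1:, :]
        boundary[1:, :] |= out[:-1, :] != out[1:, :]
        boundary[:, :-1] |= out[:, :-1] != out[:, 1:]
        boundary[:, 1:] |= out[:, :-1] != out[:, 1:]
        idx = np.flatnonzero(boundary)
        n_flip = int(perturb.flip_fraction * idx.size)
        if n_flip:
            chosen = rng.choice(idx, size=n_flip, replace=False)
            r, c = np.unravel_index(chosen, out.shape)
            offs = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
            pick = offs[rng.integers(0, 4, size=n_flip)]
            nr = np.clip(r + pick[:, 0], 0, rows - 1)
            nc = np.clip(c + pick[:, 1], 0, cols - 1)
            out[r, c] = out[nr, nc]

    if out is labels:
        out = labels.copy()
    return LabelMask(labels=out)


def _mean_dice(truth: LabelMask, tissue, jitter: float, seeds, sigma: float) -> float:
    from .agreement import dice

    vals = [
        dice(simulate_rater(truth, RaterPerturbSpec(jitter, 0.0, seed=s, smooth_sigma_px=sigma)),
             truth, tissue)
        for s in seeds
    ]
    return float(np.mean(vals))


def calibrate_rater(
    target_dice: float,
    tissue,
    spec: PhantomSpec | None = None,
    n_seeds: int = 50,
    tol: float = 0.01,
    jitter_hi: float = 24.0,
    base_seed: int = 20_001,
    smooth_sigma_px: float = 8.0,
) -> tuple[RaterPerturbSpec, float]:
    """Find the boundary jitter whose mean Dice vs truth hits ``target_dice``.

    Mean Dice over ``n_seeds`` simulated raters decreases monotonically with
    jitter (common random seeds), so a bisection brackets the target; the
    search stops when the achieved mean is within ± ``tol``.  Returns the
    perturbation spec and the achieved mean.  Unreachable targets raise with
    the bracketing (jitter, Dice) values.
    """
    if not 0 < target_dice <= 1:
        raise ValueError("target_dice must lie in (0, 1]")
    case = generate_phantom(spec or PhantomSpec())
    truth = case.truth
    seeds = [base_seed + i for i in range(n_seeds)]

    if target_dice == 1.0:
        return RaterPerturbSpec(0.0, 0.0, seed=base_seed, smooth_sigma_px=smooth_sigma_px), 1.0

    lo, f_lo = 0.0, 1.0
    hi = jitter_hi
    f_hi = _mean_dice(truth, tissue, hi, seeds, smooth_sigma_px)
    if f_hi > target_dice + tol:
        raise ValueError(
            f"target Dice {target_dice} unreachable: bracket "
            f"jitter [{lo}, {hi}] px gives Dice [{f_lo:.4f}, {f_hi:.4f}]"
        )

    best_j, best_f = hi, f_hi
    for _ in range(40):
        mid = (lo + hi) / 2
        f_mid = _mean_dice(truth, tissue, mid, seeds, smooth_sigma_px)
        if abs(f_mid - target_dice) < abs(best_f - target_dice):
            best_j, best_f = mid, f_mid
        if abs(f_mid - target_dice) <= tol:
            best_j, best_f = mid, f_mid
            break
        if f_mid > target_dice:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        if hi - lo < 1e-4:
            break
    if abs(best_f - target_dice) > tol:
        raise ValueError(
            f"calibration did not converge to {target_dice} ± {tol}: bracket "
            f"jitter [{lo:.4f}, {hi:.4f}] px gives Dice [{f_lo:.4f}, {f_hi:.4f}]"
        )
    return (
        RaterPerturbSpec(best_j, 0.0, seed=base_seed, smooth_sigma_px=smooth_sigma_px),
        best_f,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    variation: float = 0.2,
    seed: int = 0,
) -> list[PhantomCase]:
    """n phantoms with geometry jittered within ± ``variation`` of the base.

    Semi-axes, shell thicknesses, vertebra radius and visceral fat fraction
    are each scaled by an independent uniform factor in [1−v, 1+v], so truth
    areas vary across the cohort (between-subject variance for ICC).  The
    i-th case's HU/noise seed is ``base.seed + i``; with variation 0 and
    n = 1 the cohort reduces to ``generate_phantom(base_spec)`` exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if variation < 0:
        raise ValueError("variation must be >= 0")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        f = rng.uniform(1 - variation, 1 + variation, size=6)
        spec_i = replace(
            base,
            semi_axis_row_mm=base.semi_axis_row_mm * f[0],
            semi_axis_col_mm=base.semi_axis_col_mm * f[1],
            sat_ring_mm=base.sat_ring_mm * f[2],
            muscle_wall_mm=base.muscle_wall_mm * f[3],
            vertebra_radius_mm=base.vertebra_radius_mm * f[4],
            visceral_fat_fraction=min(1.0, base.visceral_fat_fraction * f[5]),
            seed=int((base.seed + i) % (2 ** 31)),
        )
        cases.append(generate_phantom(spec_i))
    return cases


# ---------------------------------------------------------------------------
# DICOM export
# ---------------------------------------------------------------------------

def write_phantom_dicom(ct: CTSlice, path) -> None:
    """Write a CTSlice as a single-frame CT DICOM (slope 1, intercept −1024).

    Stored values are 16-bit unsigned ``round(HU) + 1024``, the common CT
    encoding, so a re-read recovers the HU raster to integer quantisation.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = Dataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = pydicom.uid.CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = ct.source_id or "phantom"
    ds.Rows, ds.Columns = ct.hu.shape
    ds.PixelSpacing = [f"{ct.spacing_row_mm:g}", f"{ct.spacing_col_mm:g}"]
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "-1024"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    stored = np.clip(np.rint(ct.hu) + 1024, 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
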