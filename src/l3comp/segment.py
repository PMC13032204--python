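"""HU-threshold segmentation of an axial L3 slice and area quantification.

The pipeline is the classical threshold-plus-morphology approach to
single-slice body composition:

1. ``body_mask`` — separate the patient cross-section from air and the
   scanner table (threshold, closing, hole fill, largest component).
2. ``threshold_tissues`` — per-pixel HU classification into fat-range
   (−190..−30 HU) and muscle-range (−29..+150 HU) candidates.  HU are rounded
   to the nearest integer first, so the two printed integer ranges tile the
   HU axis with no gap between −30 and −29.
3. ``compartmentalize`` — split the body into the subcutaneous region, the
   abdominal muscle wall and the visceral cavity using connected components
   and morphological closing of the muscle candidates.
4. ``classify`` — intersect candidates with compartments: SAT, VAT, IMAT,
   MUSCLE, OTHER, BACKGROUND.
5. ``compute_areas`` — area_cm2 = pixel count × row_mm × col_mm ÷ 100.

Anything in the muscle HU range that does not belong to the wall (bowel,
organs) ends up OTHER; bone (> +150 HU) is in no range and is OTHER as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .ct_io import CTSlice, LabelMask, TISSUE_CODES

__all__ = [
    "HURanges",
    "SegmentationParams",
    "AreaReport",
    "NoBodyFoundError",
    "body_mask",
    "threshold_tissues",
    "compartmentalize",
    "classify",
    "compute_areas",
    "remove_small_components",
]


class NoBodyFoundError(ValueError):
    """No pixel exceeds the body threshold: nothing to segment."""


@dataclass(frozen=True)
class HURanges:
    """Inclusive HU windows for the two tissue candidates.

    Defaults are the standard adipose (−190..−30 HU) and skeletal muscle
    (−29..+150 HU) windows used in CT body-composition work.  Both endpoints
    of each range are inclusive; HU are rounded to integers before comparison.
    """

    fat_lo: int = -190
    fat_hi: int = -30
    muscle_lo: int = -29
    muscle_hi: int = 150

    def __post_init__(self) -> None:
        if not (self.fat_lo <= self.fat_hi < self.muscle_lo <= self.muscle_hi):
            raise ValueError(
                "require fat_lo <= fat_hi < muscle_lo <= muscle_hi, got "
                f"({self.fat_lo}, {self.fat_hi}, {self.muscle_lo}, {self.muscle_hi})"
            )


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the morphological compartmentalization.

    body_threshold_hu
        Pixels at or above this HU are body candidates (default −500,
        midway between air and fat).
    closing_radius_px
        Disk radius for morphological closing of the muscle wall; seals
        small anatomical gaps so the visceral cavity stays enclosed.
    min_component_px
        Muscle-wall components smaller than this are discarded as speckle.
    connectivity
        4 or 8 for connected components (8 default; hole filling uses the
        complementary 4-connectivity for the background).
    merge_imat_into_muscle
        Sensitivity switch: count intramuscular fat as part of MUSCLE.
    """

    body_threshold_hu: float = -500.0
    closing_radius_px: int = 3
    min_component_px: int = 10
    connectivity: int = 8
    merge_imat_into_muscle: bool = False

    def __post_init__(self) -> None:
        if self.closing_radius_px < 0 or self.min_component_px < 0:
            raise ValueError("closing_radius_px and min_component_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def _cc(self) -> int:
        # scipy/skimage connectivity: 1 = 4-neighbourhood, 2 = 8-neighbourhood
        return 1 if self.connectivity == 4 else 2


@dataclass(frozen=True)
class AreaReport:
    """Per-tissue cross-sectional areas for one slice.

    Each area is exactly ``pixel_count × spacing_row_mm × spacing_col_mm / 100``
    (mm² → cm²).
    """

    pixel_counts: dict
    spacing_row_mm: float
    spacing_col_mm: float

    def area_cm2(self, tissue: str) -> float:
        return self.pixel_counts[tissue] * self.spacing_row_mm * self.spacing_col_mm / 100

    @property
    def sat_cm2(self) -> float:
        return self.area_cm2("SAT")

    @property
    def vat_cm2(self) -> float:
        return self.area_cm2("VAT")

    @property
    def imat_cm2(self) -> float:
        return self.area_cm2("IMAT")

    @property
    def muscle_cm2(self) -> float:
        return self.area_cm2("MUSCLE")

    def to_dict(self) -> dict:
        d = {f"{name.lower()}_cm2": self.area_cm2(name) for name in TISSUE_CODES}
        d.update({f"{name.lower()}_px": int(self.pixel_counts[name]) for name in TISSUE_CODES})
        d["spacing_row_mm"] = self.spacing_row_mm
        d["spacing_col_mm"] = self.spacing_col_mm
        return d


def compute_areas(mask: LabelMask, spacing_row_mm: float, spacing_col_mm: float) -> AreaReport:
    """Quantify per-tissue areas from a label mask and the pixel spacing."""
    if spacing_row_mm <= 0 or spacing_col_mm <= 0:
        raise ValueError("pixel spacings must be > 0")
    return AreaReport(
        pixel_counts=mask.counts(),
        spacing_row_mm=float(spacing_row_mm),
        spacing_col_mm=float(spacing_col_mm),
    )


def remove_small_components(mask: np.ndarray, min_px: int, connectivity: int = 8) -> np.ndarray:
    """Drop connected components with fewer than ``min_px`` pixels."""
    if min_px < 0:
        raise ValueError("min_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if min_px == 0:
        return mask.copy()
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def _round_hu(hu: np.ndarray) -> np.ndarray:
    # np.rint rounds .5 to even; CT HU are natively integer so ties are
    # essentially absent in real data and deterministic either way.
    return np.rint(hu)


def body_mask(ct: CTSlice, params: SegmentationParams | None = None) -> np.ndarray:
    """Binary mask of the patient cross-section.

    Largest connected component of {HU >= body_threshold_hu} after
    morphological closing, hole-filled.  Detached objects (scanner table,
    cables) are discarded with the smaller components.  Ties for largest are
    broken by the smaller top-left (row-major) pixel index.
    """
    params = params or SegmentationParams()
    cand = _round_hu(ct.hu) >= params.body_threshold_hu
    if not cand.any():
        raise NoBodyFoundError("no body found: no pixel at or above the body threshold")
    if params.closing_radius_px > 0:
        cand = ndimage.binary_closing(cand, structure=morphology.disk(params.closing_radius_px))
    structure = ndimage.generate_binary_structure(2, params._cc)
    lab, n = ndimage.label(cand, structure=structure)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = sizes.max()
    # tie-break: ndimage.label assigns ids in raster-scan order, so the
    # smallest id among the maxima is the one whose first pixel comes first
    largest = int(np.flatnonzero(sizes == best)[0])
    body = lab == largest
    # 4-connected background complement avoids the dual-connectivity paradox
    body = ndimage.binary_fill_holes(body, structure=ndimage.generate_binary_structure(2, 1))
    return body


def threshold_tissues(ct: CTSlice, ranges: HURanges | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Fat-range and muscle-range candidate masks (disjoint by construction)."""
    ranges = ranges or HURanges()
    hu = _round_hu(ct.hu)
    fat = (hu >= ranges.fat_lo) & (hu <= ranges.fat_hi)
    muscle = (hu >= ranges.muscle_lo) & (hu <= ranges.muscle_hi)
    return fat, muscle


def compartmentalize(
    ct: CTSlice,
    body: np.ndarray,
    muscle_candidate: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the body into (subcutaneous_region, muscle_band, visceral_region).

    The closed muscle candidates form wall candidates; the subcutaneous
    region is every component of body ∖ wall-candidates that touches the
    body boundary; the muscle band keeps only wall-candidate components
    adjacent to the subcutaneous region (interior muscle-range tissue —
    bowel, organs — is *not* wall and falls into the visceral region);
    the visceral region is the remainder.  The three regions partition the
    body.
    """
    params = params or SegmentationParams()
    body = np.asarray(body, dtype=bool)
    if not body.any():
        raise NoBodyFoundError("empty body mask")

    wall_cand = np.asarray(muscle_candidate, dtype=bool) & body
    if params.closing_radius_px > 0 and wall_cand.any():
        wall_cand = ndimage.binary_closing(wall_cand, structure=morphology.disk(params.closing_radius_px))
        wall_cand &= body
    wall_cand = remove_small_components(wall_cand, params.min_component_px, params.connectivity)

    structure = ndimage.generate_binary_structure(2, params._cc)
    boundary = body & ~ndimage.binary_erosion(body, structure=ndimage.generate_binary_structure(2, 1))

    # components of body minus wall candidates that reach the body surface
    free = body & ~wall_cand
    lab, n = ndimage.label(free, structure=structure)
    touching = np.unique(lab[boundary & free])
    touching = touching[touching > 0]
    subcut = np.isin(lab, touching)

    # wall = closed muscle-candidate components in contact with the
    # subcutaneous region (the true abdominal wall); detached interior
    # muscle-range components belong to the visceral compartment
    band = np.zeros_like(body)
    if wall_cand.any():
        wlab, wn = ndimage.label(wall_cand, structure=structure)
        grown = ndimage.binary_dilation(subcut, structure=structure)
        adjacent = np.unique(wlab[grown & wall_cand])
        adjacent = adjacent[adjacent > 0]
        band = np.isin(wlab, adjacent)

    visceral = body & ~band & ~subcut
    if not visceral.any():
        warnings.warn(
            "muscle band does not enclose any interior region; visceral region is empty",
            stacklevel=2,
        )
    return subcut, band, visceral


def classify(
    ct: CTSlice,
    ranges: HURanges | None = None,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Full per-pixel tissue classification of one slice.

    SAT = fat ∩ subcutaneous; VAT = fat ∩ visceral; IMAT = fat ∩ muscle band;
    MUSCLE = muscle-range ∩ muscle band; OTHER = remaining body pixels
    (bone, bowel gas, organs, out-of-range HU); BACKGROUND = non-body.
    """
    ranges = ranges or HURanges()
    params = params or SegmentationParams()
    body = body_mask(ct, params)
    fat, muscle_cand = threshold_tissues(ct, ranges)
    subcut, band, visceral = compartmentalize(ct, body, muscle_cand, params)

    labels = np.zeros(ct.shape, dtype=np.uint8)
    labels[body] = TISSUE_CODES["OTHER"]
    labels[fat & subcut] = TISSUE_CODES["SAT"]
    labels[fat & visceral] = TISSUE_CODES["VAT"]
    labels[fat & band] = TISSUE_CODES["IMAT"]
    labels[muscle_cand & band] = TISSUE_CODES["MUSCLE"]
    if params.merge_imat_into_muscle:
        labels[fat & band] = TISSUE_CODES["MUSCLE"]
    return LabelMask(labels=labels)
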