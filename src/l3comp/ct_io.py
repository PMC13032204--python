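"""Reading and writing CT slices, label masks and paired measurement tables.

A :class:`CTSlice` is a calibrated Hounsfield-unit (HU) raster for a single
axial slice plus its physical pixel spacing — the unit of analysis for
single-slice body composition.  A :class:`LabelMask` carries one mutually
exclusive tissue code per pixel.  Paired area measurements (subject × rater ×
tissue) travel as long-format CSV tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CTSlice",
    "LabelMask",
    "TISSUE_CODES",
    "TISSUE_NAMES",
    "HU_MIN",
    "HU_MAX",
    "DicomReadError",
    "MaskCodeError",
    "MeasurementTableError",
    "read_ct_slice",
    "write_mask",
    "read_mask",
    "read_measurements_table",
]

#: Calibrated HU values are clipped to this range (air .. dense bone/metal).
HU_MIN = -1024.0
HU_MAX = 4000.0

#: Mutually exclusive per-pixel tissue codes.
TISSUE_CODES = {
    "BACKGROUND": 0,
    "SAT": 1,
    "VAT": 2,
    "IMAT": 3,
    "MUSCLE": 4,
    "OTHER": 5,
}
TISSUE_NAMES = {v: k for k, v in TISSUE_CODES.items()}

_VALID_CODES = frozenset(TISSUE_CODES.values())


class DicomReadError(ValueError):
    """The DICOM object cannot serve as a calibrated single-slice CT input."""


class MaskCodeError(ValueError):
    """A mask raster contains integers outside the tissue code set."""


class MeasurementTableError(ValueError):
    """A paired measurement table violates its schema."""


@dataclass(frozen=True)
class CTSlice:
    """A single axial CT slice in calibrated Hounsfield units.

    Parameters
    ----------
    hu
        2-D float raster of HU values, rows × cols.
    spacing_row_mm, spacing_col_mm
        Physical size of one pixel along the row / column axis, in mm.
        DICOM PixelSpacing order (row spacing first) is used verbatim.
    source_id
        Opaque (anonymised) identifier carried through to reports.
    """

    hu: np.ndarray
    spacing_row_mm: float
    spacing_col_mm: float
    source_id: str = ""

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 2 or hu.size == 0:
            raise ValueError("HU raster must be 2-D and non-empty")
        if not (np.isfinite(self.spacing_row_mm) and self.spacing_row_mm > 0):
            raise ValueError(f"spacing_row_mm must be finite and > 0, got {self.spacing_row_mm}")
        if not (np.isfinite(self.spacing_col_mm) and self.spacing_col_mm > 0):
            raise ValueError(f"spacing_col_mm must be finite and > 0, got {self.spacing_col_mm}")
        if not np.isfinite(hu).all():
            raise ValueError("HU raster contains non-finite values")
        if hu.min() < HU_MIN or hu.max() > HU_MAX:
            raise ValueError(
                f"HU values outside [{HU_MIN:g}, {HU_MAX:g}]: "
                f"range [{hu.min():g}, {hu.max():g}]"
            )
        object.__setattr__(self, "hu", hu)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row_mm * self.spacing_col_mm


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel tissue labels; exactly one code from :data:`TISSUE_CODES`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.size == 0:
            raise ValueError("label raster must be 2-D and non-empty")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.array_equal(labels, labels.astype(np.int64)):
                raise MaskCodeError("label raster is not integer-valued")
            labels = labels.astype(np.int64)
        bad = np.setdiff1d(np.unique(labels), sorted(_VALID_CODES))
        if bad.size:
            raise MaskCodeError(f"labels outside the tissue code set: {bad.tolist()}")
        object.__setattr__(self, "labels", labels.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def binary(self, tissue: int | str) -> np.ndarray:
        """Boolean mask of one tissue (code or name)."""
        return self.labels == _tissue_code(tissue)

    def counts(self) -> dict[str, int]:
        """Pixel count per tissue name (all six codes, zeros included)."""
        n = np.bincount(self.labels.ravel(), minlength=6)
        return {TISSUE_NAMES[c]: int(n[c]) for c in range(6)}

    def __eq__(self, other) -> bool:  # value semantics on the raster
        return isinstance(other, LabelMask) and np.array_equal(self.labels, other.labels)


def _tissue_code(tissue: int | str) -> int:
    if isinstance(tissue, str):
        try:
            return TISSUE_CODES[tissue.upper()]
        except KeyError:
            raise KeyError(f"unknown tissue {tissue!r}; expected one of {sorted(TISSUE_CODES)}")
    if int(tissue) not in _VALID_CODES:
        raise KeyError(f"unknown tissue code {tissue}")
    return int(tissue)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_ct_slice(path) -> CTSlice:
    """Read a single-frame CT DICOM file into a calibrated :class:`CTSlice`.

    Stored pixel values are mapped to HU with the rescale slope/intercept;
    PixelSpacing is taken in DICOM (row, column) order.  Rescale attributes
    missing → slope 1 / intercept 0 with a warning.  Missing PixelSpacing,
    non-CT modality or multi-frame objects are hard errors.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))

    modality = getattr(ds, "Modality", None)
    if modality != "CT":
        raise DicomReadError(f"{path}: modality {modality!r} is not CT")
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames != 1:
        raise DicomReadError(f"{path}: multi-frame object with {n_frames} frames; expected a single slice")
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None or len(spacing) != 2:
        raise DicomReadError(f"{path}: PixelSpacing missing; area computation is impossible")

    slope = getattr(ds, "RescaleSlope", None)
    intercept = getattr(ds, "RescaleIntercept", None)
    if slope is None or intercept is None:
        warnings.warn(
            f"{path}: rescale attributes missing; assuming slope=1, intercept=0",
            stacklevel=2,
        )
        slope = 1.0 if slope is None else slope
        intercept = 0.0 if intercept is None else intercept

    hu = ds.pixel_array.astype(float) * float(slope) + float(intercept)
    # Clip to the calibrated HU range; values outside arise only from
    # overflow-ish encodings and carry no tissue information here.
    hu = np.clip(hu, HU_MIN, HU_MAX)

    source_id = str(getattr(ds, "PatientID", "") or getattr(ds, "SOPInstanceUID", ""))
    return CTSlice(
        hu=hu,
        spacing_row_mm=float(spacing[0]),
        spacing_col_mm=float(spacing[1]),
        source_id=source_id,
    )


# ---------------------------------------------------------------------------
# Masks (indexed PNG / NIfTI by extension)
# ---------------------------------------------------------------------------

def write_mask(mask: LabelMask, path) -> None:
    """Persist a label mask losslessly; format chosen by extension.

    ``.png`` → 8-bit palette PNG; ``.nii``/``.nii.gz`` → NIfTI (uint8).
    ``read_mask(write_mask(m)) == m``.
    """
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        img = Image.fromarray(mask.labels, mode="P")
        # fixed 6-entry palette so the file is viewable; payload is the index
        palette = [0, 0, 0, 255, 255, 0, 255, 128, 0, 255, 0, 255, 200, 0, 0, 128, 128, 128]
        img.putpalette(palette + [0] * (768 - len(palette)))
        img.save(path)
    elif path.endswith(".nii") or path.endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unsupported mask extension for {path!r} (use .png, .nii or .nii.gz)")


def read_mask(path) -> LabelMask:
    """Read a label mask written by :func:`write_mask` (or any conforming raster)."""
    path = str(path)
    if path.endswith(".png"):
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=np.int64)
    elif path.endswith(".nii") or path.endswith(".nii.gz"):
        import nibabel as nib

        arr = np.asarray(nib.load(path).dataobj).astype(np.int64)
        arr = np.squeeze(arr)
    else:
        raise ValueError(f"unsupported mask extension for {path!r} (use .png, .nii or .nii.gz)")
    return LabelMask(labels=arr)  # code validation happens in the constructor


# ---------------------------------------------------------------------------
# Paired measurement tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "rater", "tissue", "area_cm2")


def read_measurements_table(path) -> pd.DataFrame:
    """Read a long-format paired measurement CSV.

    Required columns: subject_id, rater, tissue, area_cm2.  Duplicate
    (subject, rater, tissue) rows are a hard error.  Subjects present for
    only one rater (per tissue) cannot be paired; they are dropped with a
    warning.  The result is sorted, so row order in the file is irrelevant.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "rater": str, "tissue": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementTableError(f"{path}: missing required column(s) {missing}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["area_cm2"] = pd.to_numeric(df["area_cm2"], errors="raise")
    if (df["area_cm2"] < 0).any():
        bad = df.loc[df["area_cm2"] < 0]
        raise MeasurementTableError(f"{path}: negative areas for subjects {bad['subject_id'].tolist()}")

    key = ["subject_id", "rater", "tissue"]
    dups = df[df.duplicated(key, keep=False)]
    if len(dups):
        raise MeasurementTableError(
            f"{path}: duplicate (subject, rater, tissue) rows: "
            f"{sorted(set(map(tuple, dups[key].values.tolist())))}"
        )

    n_raters = df["rater"].nunique()
    counts = df.groupby(["tissue", "subject_id"])["rater"].nunique()
    incomplete = counts[counts < n_raters]
    if len(incomplete):
        drop = set(incomplete.index)  # (tissue, subject) pairs
        warnings.warn(
            f"{path}: excluding {len(drop)} unpairable (tissue, subject) combination(s): "
            f"{sorted(drop)}",
            stacklevel=2,
        )
        keep = ~df.set_index(["tissue", "subject_id"]).index.isin(drop)
        df = df.loc[keep.tolist() if hasattr(keep, "tolist") else keep]

    return df.sort_values(key).reset_index(drop=True)
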