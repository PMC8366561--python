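"""Core imaging data model: slices, ROI masks, lesions, and file I/O.

A lesion is represented by a single 2D CT slice (Hounsfield units) and the
corresponding 2D PET slice (standardized uptake values, SUV), each with its
own binary region-of-interest mask drawn on its native pixel grid.  CT and
PET grids of the same lesion may differ in size and spacing; no cross-modality
resampling is performed — texture statistics are computed per modality on the
grid the image was acquired on.

Supported formats are NIfTI-1 (read and write; masks as uint8 labelmaps) and
single-frame DICOM (read only; CT intensities are rescaled to HU via
RescaleSlope/RescaleIntercept, PET values are taken as stored, i.e. assumed
to be pre-normalized SUV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageSlice",
    "RoiMask",
    "Lesion",
    "read_image_slice",
    "read_mask",
    "read_lesion",
    "write_image_slice",
    "write_mask",
    "write_lesion",
    "select_most_avid_slice",
    "select_lesions",
    "load_manifest",
    "MANIFEST_COLUMNS",
    "SmallRoiWarning",
]

MODALITIES = ("CT", "PET")

#: Required columns of a cohort manifest CSV.  Additional columns are treated
#: as clinical covariates.
MANIFEST_COLUMNS = [
    "patient_id",
    "lesion_id",
    "ct_path",
    "ct_mask_path",
    "pet_path",
    "pet_mask_path",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
]

#: Masks smaller than this (in pixels) trigger a SmallRoiWarning: histogram
#: heterogeneity statistics on a handful of pixels are unstable.
DEFAULT_MIN_ROI_AREA = 10


class SmallRoiWarning(UserWarning):
    """ROI below the configured minimum pixel area."""


@dataclass
class ImageSlice:
    """A 2D scalar image with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray of shape (rows, cols)
        Intensity values — HU for CT, SUV for PET.
    spacing_mm : tuple of float
        (row, col) pixel spacing in millimetres; both strictly positive.
    modality : {"CT", "PET"}
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    modality: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]


@dataclass
class RoiMask:
    """Binary region-of-interest mask congruent with one :class:`ImageSlice`."""

    mask: np.ndarray
    lesion_id: str = ""
    patient_id: str = ""
    min_area: int = DEFAULT_MIN_ROI_AREA

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.mask.shape}")
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError("mask must contain at least one pixel")
        if n < self.min_area:
            warnings.warn(
                f"ROI {self.patient_id}/{self.lesion_id} has only {n} pixels "
                f"(< {self.min_area}); heterogeneity statistics may be unstable",
                SmallRoiWarning,
                stacklevel=2,
            )

    @property
    def area_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Lesion:
    """Paired CT and PET slices of one lesion with their ROI masks.

    The PET slice is the most tracer-avid slice through the lesion and the CT
    slice is the anatomically corresponding one; the two masks are drawn
    independently on each modality's grid.
    """

    ct_slice: ImageSlice
    pet_slice: ImageSlice
    ct_mask: RoiMask
    pet_mask: RoiMask
    lesion_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.ct_slice.modality != "CT":
            raise ValueError("ct_slice must have modality CT")
        if self.pet_slice.modality != "PET":
            raise ValueError("pet_slice must have modality PET")
        if self.ct_mask.mask.shape != self.ct_slice.shape:
            raise ValueError(
                f"CT mask shape {self.ct_mask.mask.shape} does not match "
                f"CT image shape {self.ct_slice.shape}"
            )
        if self.pet_mask.mask.shape != self.pet_slice.shape:
            raise ValueError(
                f"PET mask shape {self.pet_mask.mask.shape} does not match "
                f"PET image shape {self.pet_slice.shape}"
            )

    @property
    def pet_max(self) -> float:
        """Maximum SUV inside the PET ROI (used for avidity ranking)."""
        return float(self.pet_slice.pixels[self.pet_mask.mask].max())


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _detect_format(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".dcm", ".dicom", ".ima")):
        return "dicom"
    raise ValueError(f"cannot infer image format from {path!r}")


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a 2D slice, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    return np.asarray(data, dtype=np.float64), (float(zooms[0]), float(zooms[1]))


def _read_dicom(path: Path, modality: str) -> tuple[np.ndarray, tuple[float, float]]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-frame DICOM, got shape {arr.shape}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path}: DICOM has no PixelSpacing")
    return arr, (float(spacing[0]), float(spacing[1]))


def read_image_slice(path: str | Path, modality: str, fmt: str | None = None) -> ImageSlice:
    """Read a 2D image slice from NIfTI or single-frame DICOM."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = (fmt or _detect_format(path)).lower()
    if fmt == "nifti":
        pixels, spacing = _read_nifti(path)
    elif fmt == "dicom":
        pixels, spacing = _read_dicom(path, modality)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ImageSlice(pixels=pixels, spacing_mm=spacing, modality=modality)


def read_mask(
    path: str | Path,
    lesion_id: str = "",
    patient_id: str = "",
    fmt: str | None = None,
    min_area: int = DEFAULT_MIN_ROI_AREA,
) -> RoiMask:
    """Read a binary labelmap mask (nonzero = inside ROI)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = (fmt or _detect_format(path)).lower()
    if fmt == "nifti":
        data, _ = _read_nifti(path)
    elif fmt == "dicom":
        data, _ = _read_dicom(path, "CT")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return RoiMask(mask=data > 0, lesion_id=lesion_id, patient_id=patient_id, min_area=min_area)


def write_image_slice(slice_: ImageSlice, path: str | Path) -> None:
    """Write a slice as NIfTI-1 (int16 for CT, float32 for PET)."""
    import nibabel as nib

    dtype = np.int16 if slice_.modality == "CT" else np.float32
    data = slice_.pixels
    if slice_.modality == "CT":
        data = np.rint(data)
    affine = np.diag([slice_.spacing_mm[0], slice_.spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(dtype), affine)
    img.header.set_zooms(slice_.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: RoiMask, spacing_mm: tuple[float, float], path: str | Path) -> None:
    """Write a mask as a uint8 NIfTI labelmap."""
    import nibabel as nib

    affine = np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def read_lesion(
    ct_path: str | Path,
    ct_mask_path: str | Path,
    pet_path: str | Path,
    pet_mask_path: str | Path,
    lesion_id: str = "",
    patient_id: str = "",
    fmt: str | None = None,
    min_area: int = DEFAULT_MIN_ROI_AREA,
) -> Lesion:
    """Assemble a :class:`Lesion` from four files.

    Raises on missing files, unparsable content, or a mask whose grid does not
    match its image (checked by the Lesion constructor).
    """
    ct = read_image_slice(ct_path, "CT", fmt=fmt)
    pet = read_image_slice(pet_path, "PET", fmt=fmt)
    ct_mask = read_mask(ct_mask_path, lesion_id, patient_id, fmt=fmt, min_area=min_area)
    pet_mask = read_mask(pet_mask_path, lesion_id, patient_id, fmt=fmt, min_area=min_area)
    return Lesion(
        ct_slice=ct,
        pet_slice=pet,
        ct_mask=ct_mask,
        pet_mask=pet_mask,
        lesion_id=lesion_id,
        patient_id=patient_id,
    )


def write_lesion(lesion: Lesion, ct_path, ct_mask_path, pet_path, pet_mask_path) -> None:
    """Write all four components of a lesion as NIfTI files."""
    write_image_slice(lesion.ct_slice, ct_path)
    write_image_slice(lesion.pet_slice, pet_path)
    write_mask(lesion.ct_mask, lesion.ct_slice.spacing_mm, ct_mask_path)
    write_mask(lesion.pet_mask, lesion.pet_slice.spacing_mm, pet_mask_path)


# ---------------------------------------------------------------------------
# Slice / lesion selection
# ---------------------------------------------------------------------------

def select_most_avid_slice(
    pet_slices: Sequence[ImageSlice], masks: Sequence[RoiMask | None]
) -> int:
    """Index of the slice with the globally maximal within-ROI SUV.

    Slices whose mask is None or empty are ignored.  Ties are broken by the
    lowest index.
    """
    if len(pet_slices) != len(masks):
        raise ValueError("pet_slices and masks must have equal length")
    best_idx, best_val = -1, -np.inf
    for i, (sl, m) in enumerate(zip(pet_slices, masks)):
        if m is None or not m.mask.any():
            continue
        v = float(sl.pixels[m.mask].max())
        if v > best_val:
            best_idx, best_val = i, v
    if best_idx < 0:
        raise ValueError("all masks are empty; no avid slice to select")
    return best_idx


def select_lesions(lesions: Sequence[Lesion], limit: int = 5) -> list[Lesion]:
    """Keep the ``limit`` most PET-avid lesions, ranked by in-ROI SUVmax.

    The sort is stable: lesions with equal SUVmax keep their input order.
    """
    if len(lesions) == 0:
        raise ValueError("empty lesion list")
    if limit < 1:
        raise ValueError("limit must be >= 1")
    ranked = sorted(lesions, key=lambda les: -les.pet_max)  # stable
    return ranked[: min(limit, len(lesions))]


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV.

    One row per lesion.  Columns beyond :data:`MANIFEST_COLUMNS` are carried
    through as clinical covariates.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    for col in ("pfs_months", "os_months"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            bad = df.loc[vals.isna() | (vals < 0), "patient_id"].tolist()
            raise ValueError(f"unparseable or negative {col} for patients {bad}")
        df[col] = vals.astype(float)
    for col in ("pfs_event", "os_event"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not vals.isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
        df[col] = vals.astype(int)
    dup = df.duplicated(subset=["patient_id", "lesion_id"])
    if dup.any():
        raise ValueError(
            "duplicate (patient_id, lesion_id) rows: "
            f"{df.loc[dup, ['patient_id', 'lesion_id']].values.tolist()}"
        )
    return df


def iter_manifest_lesions(
    manifest: pd.DataFrame, root: str | Path = "."
) -> Iterable[Lesion]:
    """Yield lesions referenced by a manifest, resolving paths against root."""
    root = Path(root)
    for _, row in manifest.iterrows():
        yield read_lesion(
            root / row["ct_path"],
            root / row["ct_mask_path"],
            root / row["pet_path"],
            root / row["pet_mask_path"],
            lesion_id=str(row["lesion_id"]),
            patient_id=str(row["patient_id"]),
        )
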