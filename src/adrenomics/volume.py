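"""CT volumes, lesion masks, and VOI sampling.

A :class:`CTVolume` is a 3-D grid of attenuation values in Hounsfield units
(HU) with a voxel spacing in mm and a contrast-phase label.  Axes are ordered
``(x, y, z)`` with the third index ``k`` running over slices; voxel indices
are 0-based.  Masks are voxel-aligned binary grids on the same lattice — no
world-coordinate registration is performed or needed.

NIfTI files are read with nibabel; DICOM series directories with pydicom.
HU values are kept as floating point throughout (the DICOM reader applies
rescale slope/intercept, nothing more).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyVOIError, GeometryError, MetadataError

PHASES = ("unenhanced", "arterial", "venous", "delayed")

_SPACING_TOL = 1e-3  # mm, for volume/mask spacing agreement


@dataclass(frozen=True)
class CTVolume:
    """A 3-D HU grid with voxel spacing (mm) and contrast-phase label."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    phase: str = "unenhanced"
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or min(values.shape) < 1:
            raise GeometryError(f"volume must be 3-D with >=1 voxel per axis, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise MetadataError("volume contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise MetadataError(f"voxel spacing must be three positive lengths, got {self.spacing}")
        if self.phase not in PHASES:
            raise MetadataError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class VOIMask:
    """Binary lesion mask aligned to a :class:`CTVolume` grid."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {mask.shape}")
        if not mask.any():
            raise EmptyVOIError("mask selects no voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise MetadataError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class VOISample:
    """HU values of the masked voxels, in deterministic lexicographic
    (i, j, k) order, together with their integer voxel coordinates."""

    values: np.ndarray
    coords: np.ndarray = field(repr=False)

    @property
    def voxel_count(self) -> int:
        return int(self.values.size)


def load_volume(path: str | os.PathLike, phase: str = "unenhanced", subject_id: str = "") -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    Spacing is taken from the file header; a missing or inconsistent spacing
    raises :class:`MetadataError` naming the offending field.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        values, spacing = _read_dicom_series(path)
    else:
        values, spacing = _read_nifti(path)
    return CTVolume(values=values, spacing=spacing, phase=phase, subject_id=subject_id)


def load_mask(path: str | os.PathLike) -> VOIMask:
    """Load a binary VOI mask from a NIfTI file (non-zero voxels are in-VOI)."""
    values, spacing = _read_nifti(os.fspath(path))
    return VOIMask(mask=values != 0, spacing=spacing)


def save_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI with a diagonal affine built from its spacing."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.values, affine), os.fspath(path))


def save_mask(mask: VOIMask, path: str | os.PathLike) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), os.fspath(path))


def _read_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # unreadable / not NIfTI
        raise MetadataError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    values = np.asanyarray(img.dataobj, dtype=float)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"NIfTI header of {path!r} has invalid pixdim (voxel spacing): {zooms}")
    return values, tuple(float(z) for z in zooms)


def _read_dicom_series(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise MetadataError(f"no readable DICOM images in directory {path!r}")
    try:
        slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
        zpos = [float(ds.ImagePositionPatient[2]) for ds in slices]
    except Exception as exc:
        raise MetadataError("DICOM series lacks ImagePositionPatient") from exc
    try:
        dy, dx = (float(v) for v in slices[0].PixelSpacing)
    except Exception as exc:
        raise MetadataError("DICOM series lacks PixelSpacing") from exc
    if len(slices) > 1:
        gaps = np.diff(zpos)
        if gaps.min() <= 0 or (gaps.max() - gaps.min()) > _SPACING_TOL:
            raise MetadataError(
                f"inconsistent slice spacing (ImagePositionPatient gaps {gaps.min():.4f}..{gaps.max():.4f} mm)"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
        if dz <= 0:
            raise MetadataError("single-slice DICOM series lacks SliceThickness")
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM pixel_array is (row, col) = (y, x); transpose to (x, y), stack slices on k
    values = np.stack([p.T for p in planes], axis=-1)
    return values, (dx, dy, dz)


def extract_voi(volume: CTVolume, mask: VOIMask) -> VOISample:
    """Pull the HU values of the masked voxels out of a volume.

    Ordering is deterministic (lexicographic in (i, j, k)); every downstream
    statistic is invariant to mask storage order anyway.
    """
    if volume.shape != mask.mask.shape:
        raise GeometryError(f"volume shape {volume.shape} != mask shape {mask.mask.shape}")
    if any(abs(a - b) > _SPACING_TOL for a, b in zip(volume.spacing, mask.spacing)):
        raise GeometryError(f"volume spacing {volume.spacing} != mask spacing {mask.spacing}")
    coords = np.argwhere(mask.mask)  # lexicographic row-major order
    if coords.shape[0] == 0:
        raise EmptyVOIError("mask selects no voxels")
    values = volume.values[mask.mask]
    return VOISample(values=values, coords=coords)


def mean_densitometry(sample: VOISample) -> float:
    """Arithmetic mean HU over the VOI (the conventional densitometry value)."""
    if sample.voxel_count == 0:
        raise EmptyVOIError("empty VOI sample")
    return float(np.mean(sample.values))
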