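"""Geometric data model and medical-image I/O.

All other modules operate on three containers defined here:

``ImageVolume``
    a 3D scalar grid with physical voxel spacing and origin (mm),
``StructureMask``
    a binary grid on the same geometry (a delineated organ),
``DisplacementField``
    one 3-vector per voxel, in *voxel units per array axis*, on the
    geometry of the fixed image.

Conventions (used consistently across the package):

* voxel indices are 0-based; physical position = origin + index * spacing;
  all voxel boxes are half-open ``[lo, hi)``;
* array axis order is ``(axis0, axis1, axis2)`` and spacing/origin triples
  are stated in the same order (when reading with SimpleITK, whose native
  order is x/y/z, the triples are reversed so that they always line up with
  the numpy axes);
* only axis-aligned identity orientations are supported -- a file with a
  rotated direction matrix is rejected rather than silently reinterpreted;
* displacement vectors follow the resampling (pull-back) convention: the
  fixed-image voxel at index ``v`` corresponds to moving-image position
  ``v + field[v]``.  Millimetre magnitudes are derived on demand from the
  spacing carried alongside.

Supported formats: MetaImage (``.mha``/``.mhd``+raw) and NIfTI-1
(``.nii``/``.nii.gz``); vector fields are stored as 3-component images of
either format with a small JSON sidecar documenting component order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "StructureMask",
    "DisplacementField",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
]

_SUPPORTED_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")

_FIELD_SIDECAR = {
    "component_order": "displacement along array axes (axis0, axis1, axis2)",
    "units": "voxels per axis",
    "convention": "pull-back: fixed voxel v corresponds to moving position v + d(v)",
}


def _check_triple(name: str, value, positive: bool = False) -> tuple:
    t = tuple(float(v) for v in value)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    if positive and any(v <= 0 for v in t):
        raise ValueError(f"{name} components must be positive, got {t}")
    return t


@dataclass
class ImageVolume:
    """A 3D scalar image with axis-aligned geometry.

    Parameters
    ----------
    data : ndarray, shape (n0, n1, n2)
        Voxel intensities (HU-like, arbitrary units).
    spacing : triple of float
        Voxel size in mm along each array axis (all > 0).
    origin : triple of float
        Physical position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")
        self.spacing = _check_triple("spacing", self.spacing, positive=True)
        self.origin = _check_triple("origin", self.origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "ImageVolume | StructureMask | DisplacementField") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class StructureMask:
    """A binary organ mask aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3D, got shape {arr.shape}")
        self.data = (arr != 0).astype(np.uint8)
        self.spacing = _check_triple("spacing", self.spacing, positive=True)
        self.origin = _check_triple("origin", self.origin)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    same_geometry = ImageVolume.same_geometry


@dataclass
class DisplacementField:
    """Dense per-voxel displacement vectors (voxel units, pull-back)."""

    vectors: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"field must have shape (n0, n1, n2, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite components")
        self.spacing = _check_triple("spacing", self.spacing, positive=True)
        self.origin = _check_triple("origin", self.origin)

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]

    def magnitude_mm(self) -> np.ndarray:
        """Per-voxel displacement magnitude in mm (spacing-weighted)."""
        mm = self.vectors * np.asarray(self.spacing)[None, None, None, :]
        return np.sqrt((mm**2).sum(axis=-1))

    same_geometry = ImageVolume.same_geometry


# ---------------------------------------------------------------------------
# file I/O (SimpleITK backend)
# ---------------------------------------------------------------------------


def _check_path(path: str) -> str:
    path = os.fspath(path)
    low = path.lower()
    if not low.endswith(_SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported format for {path!r}; supported: {_SUPPORTED_SUFFIXES}"
        )
    return path


def _read_sitk(path: str) -> sitk.Image:
    path = _check_path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise ValueError(f"{path!r}: expected a 3D image, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path!r}: non-axis-aligned direction matrix {direction.tolist()} is "
            "not supported; resample the image to an identity orientation first"
        )
    return img


def _geometry_from(img: sitk.Image) -> tuple:
    # SimpleITK reports (x, y, z); numpy arrays come back as (z, y, x).
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return spacing, origin


def _sitk_from(data: np.ndarray, spacing, origin, vector: bool = False) -> sitk.Image:
    img = sitk.GetImageFromArray(data, isVector=vector)
    img.SetSpacing(tuple(float(s) for s in reversed(spacing)))
    img.SetOrigin(tuple(float(o) for o in reversed(origin)))
    return img


def read_volume(path: str) -> ImageVolume:
    """Read a scalar volume from MetaImage or NIfTI, intensities unmodified."""
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(
            f"{path!r}: expected a scalar volume, got "
            f"{img.GetNumberOfComponentsPerPixel()} components (use read_field)"
        )
    spacing, origin = _geometry_from(img)
    return ImageVolume(sitk.GetArrayFromImage(img), spacing, origin)


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume; ``read_volume`` recovers a bit-identical grid."""
    path = _check_path(path)
    sitk.WriteImage(_sitk_from(volume.data, volume.spacing, volume.origin), path)


def read_mask(path: str, reference: ImageVolume) -> StructureMask:
    """Read a structure mask aligned to ``reference``; any nonzero voxel -> 1."""
    img = _read_sitk(path)
    arr = sitk.GetArrayFromImage(img)
    if arr.shape != reference.shape:
        raise ValueError(
            f"mask {path!r} has shape {arr.shape} but the reference volume has "
            f"shape {reference.shape}"
        )
    return StructureMask(arr, reference.spacing, reference.origin)


def write_mask(mask: StructureMask, path: str) -> None:
    path = _check_path(path)
    sitk.WriteImage(_sitk_from(mask.data, mask.spacing, mask.origin), path)


def read_field(path: str) -> DisplacementField:
    """Read a 3-component vector volume as a displacement field."""
    img = _read_sitk(path)
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp != 3:
        raise ValueError(f"{path!r}: displacement field needs 3 components, got {ncomp}")
    spacing, origin = _geometry_from(img)
    return DisplacementField(sitk.GetArrayFromImage(img), spacing, origin)


def write_field(fld: DisplacementField, path: str) -> None:
    """Write a field plus a ``<path>.json`` sidecar documenting conventions."""
    path = _check_path(path)
    sitk.WriteImage(_sitk_from(fld.vectors, fld.spacing, fld.origin, vector=True), path)
    with open(path + ".json", "w") as fh:
        json.dump(_FIELD_SIDECAR, fh, indent=2)
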