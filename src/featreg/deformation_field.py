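"""From accepted featurelet displacements to a dense deformation field.

Misregistered featurelets must not mislead the interpolation, so a
restriction on the final merit value is imposed first
(:func:`filter_by_merit`): a featurelet is accepted iff its optimizer
converged, its merit is non-degenerate and the merit value reaches the
configured threshold (defaults: NC >= 0.5, MI >= 0.1 nats).

Accepted displacements live on the regular lattice of featurelet centers
(truncated edge featurelets keep their true centers).  Rejected lattice
nodes are filled with the value of the nearest accepted node, and each
displacement component is then interpolated trilinearly to every voxel;
outside the lattice hull the field clamps to the edge value.  At an
accepted node's center the interpolated field reproduces that node's
displacement exactly.

Warping follows the resampling (pull-back) convention: output voxel ``v``
takes the input sampled at ``v + field(v)`` -- linear interpolation for
images, nearest-neighbour for binary masks (contour propagation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt, map_coordinates

from .featurelet_registration import Featurelet, RegistrationConfig
from .volume_io import DisplacementField, ImageVolume, StructureMask

__all__ = [
    "ControlPointSet",
    "MeritFilterError",
    "filter_by_merit",
    "interpolate_field",
    "warp_image",
    "warp_mask",
    "field_error_voxels",
]


class MeritFilterError(RuntimeError):
    """Raised when the merit restriction rejects every featurelet."""


@dataclass
class ControlPointSet:
    """Featurelet-center lattice of displacements with validity flags."""

    centers: tuple  # per-axis arrays of lattice center coordinates (voxels)
    displacements: np.ndarray  # (*lattice_shape, 3)
    valid: np.ndarray  # (*lattice_shape,) bool

    def __post_init__(self):
        self.centers = tuple(np.asarray(c, dtype=np.float64) for c in self.centers)
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        shape = tuple(len(c) for c in self.centers)
        if self.displacements.shape != shape + (3,) or self.valid.shape != shape:
            raise ValueError("lattice arrays inconsistent with center coordinates")
        if self.valid.any() and not np.all(
            np.isfinite(self.displacements[self.valid])
        ):
            raise ValueError("valid control nodes must carry finite displacements")

    @property
    def lattice_shape(self) -> tuple:
        return tuple(len(c) for c in self.centers)


def filter_by_merit(featurelets: list, config: RegistrationConfig) -> ControlPointSet:
    """Apply the final-merit restriction and arrange survivors on the lattice.

    Acceptance: converged AND non-degenerate merit AND merit value >= the
    (per-metric) threshold.  Flags are written back onto the featurelets.
    Raises :class:`MeritFilterError` if nothing survives.
    """
    if not featurelets:
        raise ValueError("no featurelets to filter")
    threshold = config.effective_merit_threshold()

    lattice_shape = tuple(
        max(f.grid_index[axis] for f in featurelets) + 1 for axis in range(3)
    )
    centers = [np.full(n, np.nan) for n in lattice_shape]
    displacements = np.zeros(lattice_shape + (3,))
    valid = np.zeros(lattice_shape, dtype=bool)

    n_accepted = 0
    for f in featurelets:
        merit = f.final_merit
        f.accepted = bool(
            f.converged
            and merit is not None
            and not merit.degenerate
            and merit.value >= threshold
        )
        for axis in range(3):
            centers[axis][f.grid_index[axis]] = f.moving_region.center[axis]
        if f.accepted:
            displacements[f.grid_index] = f.displacement
            valid[f.grid_index] = True
            n_accepted += 1

    if n_accepted == 0:
        raise MeritFilterError(
            f"all {len(featurelets)} featurelets were rejected at merit threshold "
            f"{threshold} ({config.metric.value}); relax merit_threshold or check "
            "that the inputs are pre-aligned"
        )
    return ControlPointSet(tuple(centers), displacements, valid)


def _infill_invalid(controls: ControlPointSet) -> np.ndarray:
    """Replace rejected nodes by the nearest valid node's displacement."""
    disp = controls.displacements.copy()
    if controls.valid.all():
        return disp
    _, idx = distance_transform_edt(~controls.valid, return_indices=True)
    return disp[tuple(idx)]


def interpolate_field(controls: ControlPointSet, geometry) -> DisplacementField:
    """Trilinearly interpolate lattice displacements to every voxel.

    ``geometry`` supplies shape/spacing/origin (any of the volume_io
    containers).  Voxels outside the lattice hull take the clamped edge
    value; each vector component is interpolated separately.
    """
    if not controls.valid.any():
        raise ValueError("need at least one valid control node")
    disp = _infill_invalid(controls)

    # guard 1-node axes: duplicate the plane so trilinear interp is defined
    centers = []
    for axis, c in enumerate(controls.centers):
        if len(c) == 1:
            centers.append(np.array([c[0] - 0.5, c[0] + 0.5]))
            disp = np.repeat(disp, 2, axis=axis)
        else:
            centers.append(c)

    shape = geometry.shape
    query = np.indices(shape, dtype=np.float64).reshape(3, -1).T
    for axis in range(3):  # clamp-to-edge beyond the lattice hull
        np.clip(
            query[:, axis], centers[axis][0], centers[axis][-1], out=query[:, axis]
        )
    vectors = np.empty(shape + (3,))
    for comp in range(3):
        rgi = RegularGridInterpolator(centers, disp[..., comp], method="linear")
        vectors[..., comp] = rgi(query).reshape(shape)
    return DisplacementField(vectors, geometry.spacing, geometry.origin)


def _warp_coords(field: DisplacementField) -> np.ndarray:
    idx = np.indices(field.shape, dtype=np.float64)
    return idx + np.moveaxis(field.vectors, -1, 0)


def warp_image(image: ImageVolume, field: DisplacementField) -> ImageVolume:
    """Resample ``image`` through the field (linear interp, clamp-to-edge)."""
    if not image.same_geometry(field):
        raise ValueError("image and field geometries differ")
    data = map_coordinates(
        np.asarray(image.data, dtype=np.float64),
        _warp_coords(field),
        order=1,
        mode="nearest",
    )
    return ImageVolume(data, image.spacing, image.origin)


def warp_mask(mask: StructureMask, field: DisplacementField) -> StructureMask:
    """Propagate a binary mask through the field (nearest-neighbour)."""
    if not mask.same_geometry(field):
        raise ValueError("mask and field geometries differ")
    data = map_coordinates(mask.data, _warp_coords(field), order=0, mode="nearest")
    return StructureMask(data, mask.spacing, mask.origin)


def field_error_voxels(
    estimated: DisplacementField,
    truth: DisplacementField,
    mask: StructureMask | None = None,
) -> float:
    """Mean Euclidean error (voxels) between two fields, optionally masked."""
    if estimated.shape != truth.shape:
        raise ValueError("field shapes differ")
    err = np.linalg.norm(estimated.vectors - truth.vectors, axis=-1)
    if mask is not None:
        if mask.shape != estimated.shape:
            raise ValueError("mask shape differs from field shape")
        err = err[mask.data > 0]
        if err.size == 0:
            raise ValueError("mask is empty")
    return float(err.mean())
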