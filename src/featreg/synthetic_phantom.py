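"""Digital deformable pelvis phantom with analytic ground-truth fields.

Emulates a purpose-built physical pelvis phantom at desk scale: a
water-filled box containing an inflatable bladder balloon (200-400 cc),
a rigid prostate-shaped insert of ~110 cc glued to it, a fixed
rectum-like tube posterior to the prostate, and lateral radio-opaque
bone blocks.  The default grid is 96 x 96 x 64 voxels at 4 mm isotropic
spacing (384 x 384 x 256 mm), a scaled-down analogue of the physical
40 x 40 x 29 cm box that preserves the featurelet/search-region size
ratio of the registration defaults.

Unlike the physical phantom, whose ground truth is established by manual
delineation, the digital phantom is deformed by an *analytic* smooth
displacement field (radial bladder inflation with Gaussian falloff, a
blended rigid prostate translation, and an identically zero field on the
dilated rectum), so the true deformation is known by construction and
every pipeline stage can be scored against it.

A CBCT-like appearance for intermodality experiments is produced by a
strictly monotone nonlinear intensity remap, a multiplicative
low-frequency shading ramp and extra noise (geometry and masks are
untouched).  The default remap/shading are deliberately a worst case for
the normalized-correlation metric: soft-tissue contrast is compressed
onto a large pedestal so the shading ramp inside one featurelet dwarfs
the remaining affine signal, while histogram binning still separates the
tissue classes -- the mechanism by which mutual information survives
intermodality registration where correlation does not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation

from .deformation_field import warp_image, warp_mask
from .volume_io import DisplacementField, ImageVolume, StructureMask

__all__ = [
    "PhantomSpec",
    "GroundTruthDeformation",
    "PhantomScene",
    "generate_phantom",
    "deform_phantom",
    "simulate_cbct_appearance",
    "default_cbct_remap",
    "make_benchmark_pair",
]

STRUCTURES = ("bladder", "prostate", "rectum", "bone")

#: relative grid positions of the structure centers; the prostate sits near
#: a featurelet-cell center of the default 15^3 lattice, the rectum far
#: enough posterior that both deformation components stay < 0.5 voxel
#: within one voxel of it (keeping the rectum reference exactly invariant)
_PROSTATE_CENTER_FRAC = (0.547, 0.547, 0.586)
_RECTUM_Y_FRAC = 0.75
_RECTUM_RADIUS_MM = 16.0
_RECTUM_Z_FRAC = (0.2, 0.8)
_BONE_X_FRAC = ((0.06, 0.17), (0.83, 0.94))
_BONE_Y_FRAC = (0.40, 0.85)
_BONE_Z_FRAC = (0.15, 0.85)


@dataclass
class PhantomSpec:
    """Geometry, intensity levels and acquisition noise of the phantom.

    Intensities are HU-like: water background 0, iodine-soap bladder fill
    120, polystyrene prostate -35, bead-filled rectum 200, plaster bone
    700 -- five pairwise distinct levels.
    """

    grid_dims: tuple = (96, 96, 64)
    spacing: tuple = (4.0, 4.0, 4.0)
    intensity_background: float = 0.0
    intensity_bladder: float = 120.0
    intensity_prostate: float = -35.0
    intensity_rectum: float = 200.0
    intensity_bone: float = 700.0
    bladder_volume_cc: float = 250.0
    prostate_volume_cc: float = 110.0
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_dims) != 3 or min(self.grid_dims) < 8:
            raise ValueError("grid_dims must be a triple of at least 8 voxels")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        levels = [
            self.intensity_background,
            self.intensity_bladder,
            self.intensity_prostate,
            self.intensity_rectum,
            self.intensity_bone,
        ]
        if len(set(levels)) != 5:
            raise ValueError("the five intensity levels must be pairwise distinct")
        if not (200.0 <= self.bladder_volume_cc <= 400.0):
            raise ValueError("bladder_volume_cc must lie in [200, 400] cc")
        if self.prostate_volume_cc <= 0 or self.noise_sd < 0:
            raise ValueError("prostate volume must be > 0 and noise_sd >= 0")


@dataclass
class GroundTruthDeformation:
    """Parameters of the analytic deformation applied to a baseline scene.

    ``bladder_inflation`` is the linear scale factor of the bladder
    (volume scales with its cube); ``prostate_shift_mm`` translates the
    rigid prostate, blended to zero with a Gaussian of width
    ``prostate_falloff_mm`` outside a plateau covering the insert; the
    field is identically zero on the rectum dilated by one voxel.  With
    ``resample_noise_sd`` set, the deformed scene is re-rendered from the
    clean geometry with a fresh noise realization (two independent
    acquisitions); otherwise the noisy baseline volume is warped, so the
    zero-parameter deformation is the exact identity.
    """

    bladder_inflation: float = 1.17
    prostate_shift_mm: tuple = (12.0, 8.0, 0.0)
    bladder_falloff_mm: float = 64.0
    prostate_falloff_mm: float = 16.0
    max_amplitude_voxels: float = 7.0
    resample_noise_sd: float | None = None
    noise_seed: int = 1

    def __post_init__(self):
        self.prostate_shift_mm = tuple(float(v) for v in self.prostate_shift_mm)
        if self.bladder_inflation < 1.0:
            raise ValueError("bladder_inflation must be >= 1 (deflation unsupported)")
        if self.bladder_falloff_mm <= 0 or self.prostate_falloff_mm <= 0:
            raise ValueError("falloff scales must be positive")


@dataclass
class PhantomScene:
    """A phantom volume, its structure masks and (if deformed) the truth field."""

    volume: ImageVolume
    masks: dict
    truth_field: DisplacementField | None = None
    clean_volume: ImageVolume | None = None
    spec: PhantomSpec | None = None

    def __post_init__(self):
        missing = [s for s in STRUCTURES if s not in self.masks]
        if missing:
            raise ValueError(f"scene is missing masks: {missing}")
        for name, m in self.masks.items():
            if (m.data > 0).sum() == 0:
                raise ValueError(f"mask {name!r} is empty")
        stacked = np.stack([self.masks[s].data for s in STRUCTURES])
        if (stacked.sum(axis=0) > 1).any():
            raise ValueError("structure masks overlap")


def _solve_scale(indicator, target_voxels: int, lo: float, hi: float) -> float:
    """Bisect a monotone shape-scale parameter to hit a target voxel count."""
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if indicator(mid).sum() < target_voxels:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomScene:
    """Build the baseline phantom scene from a :class:`PhantomSpec`.

    Structure sizes are solved by bisection on the voxelized shapes, so
    mask volumes land within voxelization error of the requested cc.
    Gaussian acquisition noise (sd ``noise_sd``) is added with the fixed
    seed; masks follow the noiseless geometry.
    """
    spec = spec if spec is not None else PhantomSpec()
    dims = np.asarray(spec.grid_dims)
    sp = np.asarray(spec.spacing)
    voxel_mm3 = float(np.prod(sp))
    ii, jj, kk = np.indices(spec.grid_dims, dtype=np.float64)

    c_p = dims * np.asarray(_PROSTATE_CENTER_FRAC)

    # prostate: ellipsoid (a, a, 0.9 a) with a flattened inferior base
    def prostate_at(a):
        e = (
            ((ii - c_p[0]) / a) ** 2
            + ((jj - c_p[1]) / a) ** 2
            + ((kk - c_p[2]) / (0.9 * a)) ** 2
        ) <= 1.0
        return e & (kk - c_p[2] >= -0.7 * 0.9 * a)

    target_p = spec.prostate_volume_cc * 1000.0 / voxel_mm3
    a_p = _solve_scale(prostate_at, target_p, 1.0, float(dims.min()) / 2.0)
    prostate = prostate_at(a_p)

    # bladder: slightly anisotropic ellipsoid abutting the prostate superiorly
    target_b = spec.bladder_volume_cc * 1000.0 / voxel_mm3
    r_est = (3.0 * target_b / (4.0 * np.pi)) ** (1.0 / 3.0)

    def bladder_at(r, center=None):
        c = center if center is not None else c_p - np.array([0.0, a_p + 0.9 * r_est, 0.0])
        return (
            ((ii - c[0]) / (1.05 * r)) ** 2
            + ((jj - c[1]) / r) ** 2
            + ((kk - c[2]) / (0.95 * r)) ** 2
        ) <= 1.0

    r_b = _solve_scale(bladder_at, target_b, 1.0, float(dims.min()) / 2.0)
    bladder = bladder_at(r_b) & ~prostate

    # rectum: fixed tube posterior to the prostate, along the axial axis
    y_r = dims[1] * _RECTUM_Y_FRAC
    r_r = _RECTUM_RADIUS_MM / float(sp[1])
    z_lo, z_hi = dims[2] * _RECTUM_Z_FRAC[0], dims[2] * _RECTUM_Z_FRAC[1]
    rectum = (
        (((ii - c_p[0]) / r_r) ** 2 + ((jj - y_r) / r_r) ** 2 <= 1.0)
        & (kk >= z_lo)
        & (kk < z_hi)
    )
    rectum &= ~(prostate | bladder)

    # bone: two lateral high-intensity blocks
    bone = np.zeros(spec.grid_dims, dtype=bool)
    for x_lo, x_hi in _BONE_X_FRAC:
        bone |= (
            (ii >= dims[0] * x_lo)
            & (ii < dims[0] * x_hi)
            & (jj >= dims[1] * _BONE_Y_FRAC[0])
            & (jj < dims[1] * _BONE_Y_FRAC[1])
            & (kk >= dims[2] * _BONE_Z_FRAC[0])
            & (kk < dims[2] * _BONE_Z_FRAC[1])
        )
    bone &= ~(prostate | bladder | rectum)

    clean = np.full(spec.grid_dims, spec.intensity_background, dtype=np.float64)
    clean[bone] = spec.intensity_bone
    clean[rectum] = spec.intensity_rectum
    clean[bladder] = spec.intensity_bladder
    clean[prostate] = spec.intensity_prostate

    data = clean
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = clean + rng.normal(0.0, spec.noise_sd, size=spec.grid_dims)

    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    masks = {
        "bladder": StructureMask(bladder, **geom),
        "prostate": StructureMask(prostate, **geom),
        "rectum": StructureMask(rectum, **geom),
        "bone": StructureMask(bone, **geom),
    }
    return PhantomScene(
        volume=ImageVolume(data, **geom),
        masks=masks,
        clean_volume=ImageVolume(clean, **geom),
        spec=spec,
    )


def ground_truth_field(scene: PhantomScene, deformation: GroundTruthDeformation) -> DisplacementField:
    """Evaluate the analytic pull-back field of a deformation on a scene.

    The stored vector at fixed voxel ``v`` points to the baseline position
    the deformed scene samples, so bladder inflation appears as an inward
    pull (outer voxels read inner baseline content).
    """
    spec = scene.spec if scene.spec is not None else PhantomSpec()
    sp = np.asarray(scene.volume.spacing)
    coords = np.indices(scene.volume.shape, dtype=np.float64)

    u = np.zeros(scene.volume.shape + (3,))

    # (i) radial inflation about the bladder centroid, Gaussian falloff
    s = deformation.bladder_inflation
    if s > 1.0:
        c_b = np.argwhere(scene.masks["bladder"].data > 0).mean(axis=0)
        rel = coords - c_b[:, None, None, None]
        r2 = (rel**2).sum(axis=0)
        sigma = deformation.bladder_falloff_mm / float(sp.mean())
        amp = -(1.0 - 1.0 / s) * np.exp(-r2 / (2.0 * sigma**2))
        u += np.moveaxis(rel * amp[None], 0, -1)

    # (ii) rigid prostate translation with a smooth blend outside a plateau
    t_vox = np.asarray(deformation.prostate_shift_mm) / sp
    if np.any(t_vox != 0):
        p_idx = np.argwhere(scene.masks["prostate"].data > 0)
        c_pm = p_idx.mean(axis=0)
        r_p = (3.0 * len(p_idx) / (4.0 * np.pi)) ** (1.0 / 3.0)
        plateau = r_p + float(np.linalg.norm(t_vox))
        rel = coords - c_pm[:, None, None, None]
        dist = np.sqrt((rel**2).sum(axis=0))
        sigma_p = deformation.prostate_falloff_mm / float(sp.mean())
        blend = np.exp(-np.maximum(0.0, dist - plateau) ** 2 / (2.0 * sigma_p**2))
        u += -t_vox[None, None, None, :] * blend[..., None]

    # (iii) identically zero on the rectum dilated by one voxel
    rect_dil = binary_dilation(
        scene.masks["rectum"].data > 0, np.ones((3, 3, 3), dtype=bool)
    )
    u[rect_dil] = 0.0

    amp_max = float(np.linalg.norm(u, axis=-1).max())
    if amp_max > deformation.max_amplitude_voxels:
        raise ValueError(
            f"deformation amplitude {amp_max:.2f} voxels exceeds the cap "
            f"{deformation.max_amplitude_voxels}"
        )
    return DisplacementField(u, scene.volume.spacing, scene.volume.origin)


def deform_phantom(scene: PhantomScene, deformation: GroundTruthDeformation) -> PhantomScene:
    """Warp a baseline scene by the analytic field; store the truth field.

    Volume and all masks are warped by the same field (masks with
    nearest-neighbour sampling), so warping the baseline masks with
    ``truth_field`` reproduces the deformed masks identically.
    """
    truth = ground_truth_field(scene, deformation)
    if deformation.resample_noise_sd is not None:
        if scene.clean_volume is None:
            raise ValueError("resampling noise requires the clean baseline volume")
        clean_warp = warp_image(scene.clean_volume, truth)
        rng = np.random.default_rng(deformation.noise_seed)
        data = clean_warp.data + rng.normal(
            0.0, deformation.resample_noise_sd, size=clean_warp.shape
        )
        volume = ImageVolume(data, clean_warp.spacing, clean_warp.origin)
    else:
        clean_warp = (
            warp_image(scene.clean_volume, truth) if scene.clean_volume else None
        )
        volume = warp_image(scene.volume, truth)
    masks = {name: warp_mask(m, truth) for name, m in scene.masks.items()}
    return PhantomScene(
        volume=volume,
        masks=masks,
        truth_field=truth,
        clean_volume=clean_warp,
        spec=scene.spec,
    )


def default_cbct_remap():
    """Strictly monotone intensity curve of the default CBCT surrogate.

    Soft tissue (HU-like -100..300) is compressed onto a ~900-unit
    pedestal with only ~25 units of residual contrast; the high (bone)
    range keeps a steep slope so bony anatomy stays high-contrast.
    """

    def remap(x):
        x = np.asarray(x, dtype=np.float64)
        return 900.0 + 10.0 * np.tanh((x + 10.0) / 25.0) + 0.5 * np.maximum(x - 400.0, 0.0) + 1e-6 * x

    return remap


def simulate_cbct_appearance(
    volume: ImageVolume,
    remap,
    shading_amplitude: float = 0.12,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> ImageVolume:
    """Give a volume a CBCT-like intensity appearance; geometry unchanged.

    Intensities pass through the strictly monotone ``remap`` (verified on a
    dense sample of the volume's range), are multiplied by a smooth
    first-order shading ramp of relative amplitude ``shading_amplitude``
    along the in-plane diagonal, and receive Gaussian noise.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    grid = np.linspace(lo, hi, 256) if hi > lo else np.array([lo, lo + 1.0])
    diffs = np.diff(np.asarray(remap(grid), dtype=np.float64))
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("remap must be strictly monotone over the intensity range")

    out = np.asarray(remap(data), dtype=np.float64)
    if shading_amplitude != 0.0:
        n0, n1 = volume.shape[0], volume.shape[1]
        ii, jj = np.meshgrid(
            np.arange(n0, dtype=np.float64),
            np.arange(n1, dtype=np.float64),
            indexing="ij",
        )
        proj = (ii + jj) / max(1.0, (n0 - 1) + (n1 - 1))  # in [0, 1]
        shading = 1.0 + shading_amplitude * (2.0 * proj - 1.0)
        out = out * shading[:, :, None]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return ImageVolume(out, volume.spacing, volume.origin)


def make_benchmark_pair(
    spec: PhantomSpec | None = None,
    deformation: GroundTruthDeformation | None = None,
    intermodality: bool = False,
    seed: int = 0,
) -> tuple:
    """Build a (fixed, moving) benchmark scene pair.

    The moving scene is the baseline phantom; the fixed scene is the
    deformed phantom re-rendered with an independent noise realization
    (two acquisitions), passed through the CBCT surrogate when
    ``intermodality``.  The truth field rides on the fixed scene.  All
    randomness derives from ``seed``.
    """
    spec = spec if spec is not None else PhantomSpec(seed=seed)
    if deformation is None:
        deformation = GroundTruthDeformation()
    if deformation.resample_noise_sd is None:
        deformation = replace(
            deformation, resample_noise_sd=spec.noise_sd, noise_seed=seed + 1
        )
    moving = generate_phantom(spec)
    fixed = deform_phantom(moving, deformation)
    if intermodality:
        fixed = PhantomScene(
            volume=simulate_cbct_appearance(
                fixed.volume, default_cbct_remap(), seed=seed + 2
            ),
            masks=fixed.masks,
            truth_field=fixed.truth_field,
            clean_volume=fixed.clean_volume,
            spec=fixed.spec,
        )
    return fixed, moving
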