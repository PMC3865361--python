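"""Patch-similarity measures driving the featurelet registration.

Two measures are offered, both oriented so that larger is better:

* normalized correlation (NC): the Pearson correlation of the flattened
  intensities, on [-1, 1]; invariant under positive affine rescaling of
  either patch but sensitive to any other intensity relationship;
* mutual information (MI): H(A) + H(B) - H(A, B) in nats, estimated from a
  plain joint histogram with equal-width bins spanning each patch's own
  intensity range; invariant under any intensity bijection of one patch
  that preserves bin assignment.

This asymmetry is what makes MI usable across modalities (CT vs CBCT)
where the intensity relation is monotone but far from affine, while NC is
the sharper measure within one modality.

A flat (zero-variance) patch makes NC undefined; such patches are flagged
*degenerate* (value 0) instead of raising, because uniform background (the
water filling of a pelvis phantom, for instance) produces many flat
featurelets that downstream merit filtering must simply discard.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricKind", "MetricValue", "normalized_correlation", "mutual_information"]


class MetricKind(str, enum.Enum):
    NC = "NC"
    MI = "MI"


@dataclass(frozen=True)
class MetricValue:
    """A similarity value with its kind and a degeneracy flag."""

    value: float
    kind: MetricKind
    higher_is_better: bool = True
    degenerate: bool = False


def _as_flat_pair(patch_a, patch_b) -> tuple:
    a = np.asarray(patch_a, dtype=np.float64)
    b = np.asarray(patch_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"patch shapes differ: {a.shape} vs {b.shape}")
    return a.ravel(), b.ravel()


def normalized_correlation(patch_a, patch_b) -> MetricValue:
    """Pearson correlation of two equally-shaped patches.

    Returns a degenerate ``MetricValue`` (value 0) if either patch has zero
    variance rather than dividing by zero.
    """
    a, b = _as_flat_pair(patch_a, patch_b)
    if a.size < 2:
        raise ValueError("normalized correlation needs at least 2 voxels")
    a = a - a.mean()
    b = b - b.mean()
    ssa = float(a @ a)
    ssb = float(b @ b)
    if ssa <= 0.0 or ssb <= 0.0:
        return MetricValue(0.0, MetricKind.NC, degenerate=True)
    value = float(np.clip((a @ b) / np.sqrt(ssa * ssb), -1.0, 1.0))
    return MetricValue(value, MetricKind.NC)


def nc_values(a_flat: np.ndarray, b_rows: np.ndarray) -> np.ndarray:
    """Vectorized NC of one patch against many candidates (optimizer path).

    ``a_flat`` has shape (n,), ``b_rows`` shape (m, n); rows where either
    side is flat yield 0.
    """
    a = a_flat - a_flat.mean()
    ssa = float(a @ a)
    b = b_rows - b_rows.mean(axis=1, keepdims=True)
    ssb = (b * b).sum(axis=1)
    denom = np.sqrt(ssa * ssb)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = (b @ a) / denom
    vals[~np.isfinite(vals)] = 0.0
    if ssa <= 0.0:
        vals[:] = 0.0
    return np.clip(vals, -1.0, 1.0)


def _hist_range(x: np.ndarray) -> tuple:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:  # constant patch: a single occupied bin, entropy 0
        return lo - 0.5, lo + 0.5
    return lo, hi


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(patch_a, patch_b, bins: int = 32) -> MetricValue:
    """Histogram mutual information in nats.

    Bins are ``bins`` x ``bins`` equal-width cells spanning each patch's own
    intensity range (no Parzen smoothing, no range clipping).  A constant
    patch has zero marginal entropy, hence MI = 0; the result is then
    flagged degenerate so merit filtering can discard it.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a, b = _as_flat_pair(patch_a, patch_b)
    hist, _, _ = np.histogram2d(
        a, b, bins=bins, range=[_hist_range(a), _hist_range(b)]
    )
    n = hist.sum()
    p = hist / n
    ha = _entropy(p.sum(axis=1))
    hb = _entropy(p.sum(axis=0))
    hab = _entropy(p.ravel())
    value = max(0.0, ha + hb - hab)
    degenerate = ha == 0.0 or hb == 0.0
    return MetricValue(value, MetricKind.MI, degenerate=degenerate)


def pv_mi_values(a_flat: np.ndarray, b_rows: np.ndarray, bins: int = 32) -> np.ndarray:
    """Partial-volume MI of one patch against many candidates (optimizer path).

    The hard-binned estimator of :func:`mutual_information` is piecewise
    constant in a subvoxel translation, which defeats a finite-difference
    gradient.  For optimization only, the candidate patch's intensities are
    spread linearly over the two nearest bins (partial-volume weighting, as
    in Mattes-style estimators), making the surface continuous in the
    translation.  Reported merits still use the plain histogram estimate.
    """
    a = a_flat
    ka = np.clip(
        ((a - a.min()) / max(np.ptp(a), np.finfo(float).tiny) * bins).astype(np.int64),
        0,
        bins - 1,
    )
    out = np.empty(len(b_rows))
    for i, b in enumerate(b_rows):
        lo, hi = float(b.min()), float(b.max())
        width = (hi - lo) / bins if hi > lo else 1.0
        pos = (b - lo) / width - 0.5
        j0 = np.floor(pos).astype(np.int64)
        w1 = pos - j0
        j0c = np.clip(j0, 0, bins - 1)
        j1c = np.clip(j0 + 1, 0, bins - 1)
        flat = np.bincount(ka * bins + j0c, weights=1.0 - w1, minlength=bins * bins)
        flat += np.bincount(ka * bins + j1c, weights=w1, minlength=bins * bins)
        p = flat / flat.sum()
        out[i] = (
            _entropy(p.reshape(bins, bins).sum(axis=1))
            + _entropy(p.reshape(bins, bins).sum(axis=0))
            - _entropy(p)
        )
    return out
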