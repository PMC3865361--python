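"""Contour-agreement metrics and paired statistical comparison.

Implements the quantities used to judge contour propagation:

* Dice similarity coefficient (volume overlap index) on a 0-100 scale,
  DSC = |Vd n Vm| / ((|Vd| + |Vm|)/2) x 100;
* Hausdorff distance H(A,B) = max(h(A,B), h(B,A)) with
  h(A,B) = max_{a in A} min_{b in B} ||a - b||, computed over surface
  voxels (foreground voxels with at least one face-adjacent background
  neighbour; the grid boundary counts as background), in pixels by
  default or in mm using the anisotropic spacing;
* structure volume (voxels and cc) and center of mass (mm), with the
  derived center-of-mass shift and unsigned percent volume change;
* a paired two-sided Wilcoxon signed-rank comparison with the
  NS / better / worse labelling used in clinical comparison tables.

The Wilcoxon test drops zero differences, uses the exact null
distribution of the signed midrank sum for n <= 25 (a subset-sum dynamic
programme, valid under ties) and the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .volume_io import StructureMask

__all__ = [
    "dice_coefficient",
    "hausdorff_distance",
    "mask_volume",
    "center_of_mass",
    "percent_volume_change",
    "ComparisonLabel",
    "wilcoxon_compare",
    "build_report",
]


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    if not a.same_geometry(b):
        raise ValueError(
            f"mask geometries differ: {a.shape}/{a.spacing} vs {b.shape}/{b.spacing}"
        )


def dice_coefficient(deformed: StructureMask, reference: StructureMask) -> float:
    """Dice overlap of two masks on the 0-100 scale (symmetric)."""
    _check_pair(deformed, reference)
    vd = deformed.data > 0
    vm = reference.data > 0
    total = int(vd.sum()) + int(vm.sum())
    if total == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return 100.0 * 2.0 * int((vd & vm).sum()) / total


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """Indices (n, 3) of foreground voxels with a face-adjacent background
    neighbour; voxels on the grid boundary count as surface."""
    m = mask.data > 0
    interior = binary_erosion(m, generate_binary_structure(3, 1), border_value=0)
    return np.argwhere(m & ~interior)


def hausdorff_distance(a: StructureMask, b: StructureMask, use_mm: bool = False) -> float:
    """Symmetric Hausdorff distance between two mask surfaces.

    In pixels (Euclidean on voxel indices) by default; with ``use_mm`` the
    index offsets are scaled by the voxel spacing first (relevant for
    anisotropic slice thickness).
    """
    _check_pair(a, b)
    pa = surface_voxels(a).astype(np.float64)
    pb = surface_voxels(b).astype(np.float64)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance requires two non-empty masks")
    if use_mm:
        scale = np.asarray(a.spacing)
        pa = pa * scale
        pb = pb * scale
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def mask_volume(mask: StructureMask) -> tuple:
    """Foreground voxel count and volume in cc."""
    count = int((mask.data > 0).sum())
    return count, count * mask.voxel_volume_mm3() / 1000.0


def center_of_mass(mask: StructureMask) -> tuple:
    """Mean physical position (mm) of the foreground voxels."""
    idx = np.argwhere(mask.data > 0)
    if len(idx) == 0:
        raise ValueError("center of mass of an empty mask is undefined")
    pos = idx * np.asarray(mask.spacing) + np.asarray(mask.origin)
    return tuple(float(v) for v in pos.mean(axis=0))


def percent_volume_change(after: StructureMask, before: StructureMask) -> float:
    """Unsigned percent change of foreground volume, |after-before|/before."""
    nb = int((before.data > 0).sum())
    if nb == 0:
        raise ValueError("percent volume change undefined for an empty baseline")
    na = int((after.data > 0).sum())
    return 100.0 * abs(na - nb) / nb


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonLabel:
    """Outcome of a paired method comparison."""

    label: str  # 'NS', 'better', 'worse' (method 2 relative to method 1)
    p_value: float
    alpha: float = 0.05


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank sum, valid under midrank ties.

    Enumerates the null distribution of W+ = sum of ranks with positive
    sign over all 2^n sign assignments by dynamic programming on doubled
    (integer) midranks.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = counts.sum()  # == 2**n
    w2 = int(np.rint(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum() / n_assign
    sf = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_compare(
    scores_m1,
    scores_m2,
    alpha: float = 0.05,
    higher_is_better: bool = True,
    exact_limit: int = 25,
) -> ComparisonLabel:
    """Paired two-sided Wilcoxon signed-rank test with a direction label.

    Zero differences are dropped.  With n (nonzero pairs) <= ``exact_limit``
    the exact null distribution is used; beyond that, the tie-corrected
    normal approximation.  The label reports whether method 2 is
    significantly 'better' or 'worse' than method 1 given the metric
    orientation, or 'NS'.
    """
    m1 = np.asarray(scores_m1, dtype=np.float64)
    m2 = np.asarray(scores_m2, dtype=np.float64)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("paired score lists must be 1D and equally long")
    if len(m1) < 5:
        raise ValueError("need at least 5 paired observations")
    d = m2 - m1
    nz = d[d != 0]
    if len(nz) == 0:
        return ComparisonLabel("NS", 1.0, alpha)
    if len(nz) <= exact_limit:
        ranks = stats.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(
            stats.wilcoxon(
                nz, zero_method="wilcox", alternative="two-sided", method="approx"
            ).pvalue
        )
    if p >= alpha:
        return ComparisonLabel("NS", p, alpha)
    med = float(np.median(nz))
    if med == 0.0:
        med = float(np.mean(nz))
    improved = (med > 0) == higher_is_better
    return ComparisonLabel("better" if improved else "worse", p, alpha)


def _comparison_symbol(label: ComparisonLabel) -> str:
    if label.label == "NS":
        return "NS"
    strong = label.p_value < label.alpha / 5.0
    if label.label == "better":
        return "++" if strong else "+"
    return "--" if strong else "-"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def build_report(
    method_masks: dict,
    reference_masks: dict,
    alpha: float = 0.05,
    use_mm_hausdorff: bool = False,
) -> tuple:
    """Per-structure metric table plus pairwise Wilcoxon comparison table.

    Parameters
    ----------
    method_masks : {method: {(case, structure): StructureMask}}
        Propagated masks per method.  Include the un-deformed masks under a
        method name such as ``"RR"`` to use rigid registration as baseline.
    reference_masks : {(case, structure): StructureMask}
        Masks delineated on the fixed image (the ground truth of each case).
    alpha : significance level for the comparison labels.
    use_mm_hausdorff : also computed; this flag picks which unit fills the
        comparison table.

    Returns
    -------
    (metrics, comparisons) : two pandas DataFrames.  ``metrics`` has one row
    per (case, structure, method); ``comparisons`` one row per structure,
    unordered method pair and metric, labelled NS / + / ++ / - / -- (method
    2 relative to method 1).  Pairs with fewer than 5 cases get an NS label
    with p = 1 when all differences vanish and p = NaN otherwise.
    """
    rows = []
    scores: dict = {}
    for method, masks in method_masks.items():
        for key, mask in masks.items():
            case, structure = key
            if key not in reference_masks:
                raise ValueError(f"no reference mask for case {case!r} / {structure!r}")
            ref = reference_masks[key]
            dsc = dice_coefficient(mask, ref)
            hd_px = hausdorff_distance(mask, ref, use_mm=False)
            hd_mm = hausdorff_distance(mask, ref, use_mm=True)
            nvox, cc = mask_volume(mask)
            com = center_of_mass(mask)
            com_ref = center_of_mass(ref)
            shift = float(np.linalg.norm(np.subtract(com, com_ref)))
            rows.append(
                {
                    "case": case,
                    "structure": structure,
                    "method": method,
                    "dsc": dsc,
                    "hausdorff_px": hd_px,
                    "hausdorff_mm": hd_mm,
                    "volume_voxels": nvox,
                    "volume_cc": cc,
                    "com_mm_0": com[0],
                    "com_mm_1": com[1],
                    "com_mm_2": com[2],
                    "com_shift_mm": shift,
                    "pct_volume_change": percent_volume_change(mask, ref),
                }
            )
            hd = hd_mm if use_mm_hausdorff else hd_px
            scores.setdefault((structure, method), {})[case] = (dsc, hd)
    metrics = pd.DataFrame(rows)

    methods = list(method_masks)
    structures = sorted({s for (_, s) in reference_masks})
    comp_rows = []
    for structure in structures:
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1 :]:
                s1 = scores.get((structure, m1), {})
                s2 = scores.get((structure, m2), {})
                cases = sorted(set(s1) & set(s2))
                for mi, (name, better_high) in enumerate(
                    [("DSC", True), ("Hausdorff", False)]
                ):
                    x1 = [s1[c][mi] for c in cases]
                    x2 = [s2[c][mi] for c in cases]
                    if len(cases) >= 5:
                        lbl = wilcoxon_compare(
                            x1, x2, alpha=alpha, higher_is_better=better_high
                        )
                    elif np.allclose(x1, x2):
                        lbl = ComparisonLabel("NS", 1.0, alpha)
                    else:
                        lbl = ComparisonLabel("NS", float("nan"), alpha)
                    comp_rows.append(
                        {
                            "structure": structure,
                            "method_1": m1,
                            "method_2": m2,
                            "metric": name,
                            "n": len(cases),
                            "p_value": lbl.p_value,
                            "label": _comparison_symbol(lbl),
                        }
                    )
    comparisons = pd.DataFrame(comp_rows)
    return metrics, comparisons
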