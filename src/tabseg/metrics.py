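"""Brain-restricted evaluation: continuous-map similarity (Pearson, Spearman,
MSE) and argmax-derived binary overlap/distance (Dice, Jaccard, Hausdorff),
each computed per tissue type.

Only voxels inside the brain mask participate; the mask is defined as the set
of voxels whose ground-truth channel sum is positive. Binary maps come from a
channel argmax with ties broken toward the lowest channel index (GM).
Hausdorff distances are full (100th percentile) symmetric distances between
foreground voxel centers, in physical units.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, stats

from .types import (
    OUT_OF_BRAIN,
    TISSUES,
    BrainMask,
    MetricsRecord,
    SegmentationMask,
    TissueMetrics,
    TissueProbMap,
)

__all__ = [
    "brain_restrict",
    "argmax_segmentation",
    "binary_tissue_map",
    "dice",
    "jaccard",
    "hausdorff",
    "pearson",
    "spearman",
    "mse_map",
    "evaluate",
]


def brain_restrict(probmap: TissueProbMap, mask: BrainMask, tissue: int) -> np.ndarray:
    """Values of one tissue channel at in-mask voxels, fixed raster order."""
    if probmap.spatial_shape != mask.shape:
        raise ValueError("probability map and mask shapes differ")
    if not mask.values.any():
        raise ValueError("empty brain mask")
    return probmap.values[tissue][mask.values]


def argmax_segmentation(probmap: TissueProbMap, mask: BrainMask) -> SegmentationMask:
    """Per-voxel channel argmax inside the mask; -1 outside.

    numpy's argmax takes the first maximum, which realizes the documented
    tie rule (lowest channel index wins).
    """
    if probmap.spatial_shape != mask.shape:
        raise ValueError("probability map and mask shapes differ")
    labels = np.argmax(probmap.values, axis=0).astype(np.int8)
    labels[~mask.values] = OUT_OF_BRAIN
    return SegmentationMask(labels)


def binary_tissue_map(seg: SegmentationMask, tissue: int) -> np.ndarray:
    return seg.labels == tissue


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); both-empty pairs score 1.0."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    _check_same_shape(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """|A∩B| / |A∪B|; both-empty pairs score 1.0."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    _check_same_shape(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def hausdorff(
    a: np.ndarray, b: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> float:
    """Symmetric Hausdorff distance between foreground voxel centers.

    Euclidean, in physical units (voxel indices scaled by spacing). Undefined
    (raises) when either set is empty.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    _check_same_shape(a, b)
    if not a.any() or not b.any():
        raise ValueError("Hausdorff distance undefined for an empty set")
    if np.array_equal(a, b):
        return 0.0
    # distance transform of the complement gives distance-to-nearest-foreground
    dt_b = ndimage.distance_transform_edt(~b, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~a, sampling=spacing)
    return float(max(dt_b[a].max(), dt_a[b].max()))


def _check_corr_inputs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return x, y


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_corr_inputs(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (ties get average ranks)."""
    x, y = _check_corr_inputs(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("Spearman correlation undefined for zero rank variance")
    return float(stats.pearsonr(rx, ry).statistic)


def mse_map(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    return float(np.mean((x - y) ** 2))


def evaluate(
    pred: TissueProbMap,
    gt: TissueProbMap,
    mask: BrainMask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MetricsRecord:
    """All six metrics for each tissue of one predicted/reference pair.

    Continuous metrics act on brain-restricted channel values; binary metrics
    act on per-tissue argmax maps. A Hausdorff distance that is undefined
    because a tissue is absent on one side only is recorded as NaN rather than
    aborting the whole record; both-empty pairs get Dice/Jaccard 1 and NaN
    Hausdorff.
    """
    if pred.spatial_shape != gt.spatial_shape or pred.spatial_shape != mask.shape:
        raise ValueError("pred/gt/mask shapes differ")
    seg_pred = argmax_segmentation(pred, mask)
    seg_gt = argmax_segmentation(gt, mask)
    per_tissue = []
    for tissue in range(len(TISSUES)):
        xv = brain_restrict(pred, mask, tissue)
        yv = brain_restrict(gt, mask, tissue)
        bp = binary_tissue_map(seg_pred, tissue)
        bg = binary_tissue_map(seg_gt, tissue)
        try:
            hd = hausdorff(bp, bg, spacing)
        except ValueError:
            hd = math.nan
        per_tissue.append(
            TissueMetrics(
                dice=dice(bp, bg),
                jaccard=jaccard(bp, bg),
                pearson=pearson(xv, yv),
                spearman=spearman(xv, yv),
                hausdorff=hd,
                mse=mse_map(xv, yv),
            )
        )
    return MetricsRecord(*per_tissue)
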