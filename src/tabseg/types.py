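"""Shared domain containers used across the pipeline.

Channel order is fixed package-wide: GM=0, WM=1, CSF=2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: canonical tissue channel order
TISSUES = ("GM", "WM", "CSF")
GM, WM, CSF = 0, 1, 2

#: label assigned outside the brain mask in segmentation grids
OUT_OF_BRAIN = -1

PROB_SUM_TOL = 1e-6


@dataclass
class Volume3D:
    """A scalar intensity grid (the T1w image).

    Parameters
    ----------
    values : (D, H, W) float array
    spacing : per-axis voxel size in mm
    background_value : intensity assigned outside the brain
    affine : optional 4x4 voxel-to-world matrix (NIfTI convention)
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_value: float = 0.0
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Volume3D values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class BrainMask:
    """Boolean grid; True marks brain voxels."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("BrainMask requires a 3D grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class TissueProbMap:
    """Per-voxel tissue probabilities, shape (3, D, H, W), channels GM, WM, CSF.

    Inside the brain the three channels sum to 1 (within ``PROB_SUM_TOL``);
    outside they are exactly zero.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    channel_order: tuple[str, str, str] = field(default=TISSUES, init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[0] != 3:
            raise ValueError(
                f"TissueProbMap requires shape (3, D, H, W), got {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[1:]

    def channel(self, tissue: int) -> np.ndarray:
        return self.values[tissue]

    def validate(self, mask: Optional[BrainMask] = None) -> None:
        """Raise if probabilities leave [0, 1] or in/out-of-mask sums are wrong."""
        v = self.values
        if v.min() < -PROB_SUM_TOL or v.max() > 1 + PROB_SUM_TOL:
            raise ValueError("probabilities must lie in [0, 1]")
        if mask is not None:
            s = v.sum(axis=0)
            m = mask.values
            if m.shape != s.shape:
                raise ValueError("mask shape does not match probability map")
            if not np.allclose(s[m], 1.0, atol=PROB_SUM_TOL):
                raise ValueError("in-mask channel sums must equal 1")
            if np.any(s[~m] != 0.0):
                raise ValueError("out-of-mask probabilities must be exactly 0")

    def implied_mask(self) -> BrainMask:
        """Brain mask = voxels with positive channel sum."""
        return BrainMask(self.values.sum(axis=0) > 0)


@dataclass
class SegmentationMask:
    """Integer label grid: {0=GM, 1=WM, 2=CSF} in-brain, -1 outside."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("SegmentationMask requires a 3D grid")
        inside = self.labels != OUT_OF_BRAIN
        vals = np.unique(self.labels[inside])
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("in-mask labels must lie in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class TissueMetrics:
    """The six per-tissue scores for one volume pair."""

    dice: float
    jaccard: float
    pearson: float
    spearman: float
    hausdorff: float  # physical units; NaN when undefined (empty set)
    mse: float


@dataclass
class MetricsRecord:
    """Six metrics for each of GM, WM, CSF — one evaluated volume pair."""

    gm: TissueMetrics
    wm: TissueMetrics
    csf: TissueMetrics

    def for_tissue(self, tissue: int) -> TissueMetrics:
        return (self.gm, self.wm, self.csf)[tissue]

    def to_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, tm in zip(TISSUES, (self.gm, self.wm, self.csf)):
            for metric in ("dice", "jaccard", "pearson", "spearman", "hausdorff", "mse"):
                out[f"{metric}_{name.lower()}"] = getattr(tm, metric)
        return out

    @classmethod
    def from_flat_dict(cls, d: dict[str, float]) -> "MetricsRecord":
        parts = []
        for name in TISSUES:
            parts.append(
                TissueMetrics(
                    **{
                        m: float(d[f"{m}_{name.lower()}"])
                        for m in ("dice", "jaccard", "pearson", "spearman", "hausdorff", "mse")
                    }
                )
            )
        return cls(*parts)
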