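"""Data conditioning: MIP-guided field-of-view crop/pad, [-1, 1] intensity
normalization, and ground-truth channel stacking."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import BrainMask, TissueProbMap, Volume3D

__all__ = ["FovBox", "mip_fov", "pad_crop", "normalize_minus1_1", "stack_ground_truth"]


@dataclass(frozen=True)
class FovBox:
    """Half-open per-axis bounding box: lower inclusive, upper exclusive."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise ValueError("FovBox needs 3 lower and 3 upper indices")
        for lo, hi in zip(self.lower, self.upper):
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid box extent [{lo}, {hi})")

    @property
    def extent(self) -> tuple[int, int, int]:
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    def contains(self, shape: Sequence[int]) -> bool:
        return all(hi <= s for hi, s in zip(self.upper, shape))


def mip_fov(volumes: Iterable[Volume3D]) -> FovBox:
    """Tight bounding box of above-background voxels in the across-dataset
    maximum intensity projection.

    The comparison is strict (> background); phantom backgrounds are exact.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes given")
    shape = volumes[0].shape
    bg = volumes[0].background_value
    for v in volumes:
        if v.shape != shape:
            raise ValueError(f"mixed grid shapes: {v.shape} vs {shape}")
    mip = np.maximum.reduce([v.values for v in volumes])
    fg = mip > bg
    if not fg.any():
        raise ValueError("all volumes are entirely background")
    lower, upper = [], []
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        lower.append(int(idx[0]))
        upper.append(int(idx[-1]) + 1)
    return FovBox(tuple(lower), tuple(upper))


def _centered_placement(extent: int, target: int) -> tuple[int, int]:
    """Start offset of `extent` centered in `target`; extra voxel high side."""
    pad = target - extent
    lo = pad // 2
    return lo, lo + extent


def pad_crop(volume: Volume3D, target_side: int, box: FovBox) -> Volume3D:
    """Center the FovBox content in a target_side^3 frame.

    The box content is preserved bit-exactly; padding uses the volume's
    background value. Errors if the box exceeds the target on any axis.
    """
    if target_side < 1:
        raise ValueError("target_side must be >= 1")
    if not box.contains(volume.shape):
        raise ValueError("FovBox does not fit inside the source volume")
    for ax, ext in enumerate(box.extent):
        if ext > target_side:
            raise ValueError(
                f"FovBox extent {ext} on axis {ax} exceeds target {target_side}; "
                "cropping would remove anatomy"
            )
    out = np.full((target_side,) * 3, volume.background_value, dtype=volume.values.dtype)
    placements = [_centered_placement(e, target_side) for e in box.extent]
    dst = tuple(slice(lo, hi) for lo, hi in placements)
    out[dst] = volume.values[box.slices()]
    affine = None
    if volume.affine is not None:
        # shift origin so preserved voxels keep their world coordinates
        affine = volume.affine.copy()
        shift = [box.lower[ax] - placements[ax][0] for ax in range(3)]
        affine[:3, 3] += affine[:3, :3] @ np.asarray(shift, dtype=float)
    return Volume3D(
        out,
        spacing=volume.spacing,
        background_value=volume.background_value,
        affine=affine,
    )


def pad_crop_probmap(probmap: TissueProbMap, target_side: int, box: FovBox) -> TissueProbMap:
    """Apply the same FovBox transform to a 3-channel ground-truth map."""
    channels = [
        pad_crop(Volume3D(probmap.values[c], spacing=probmap.spacing), target_side, box).values
        for c in range(3)
    ]
    return TissueProbMap(np.stack(channels), spacing=probmap.spacing)


def pad_crop_mask(mask: BrainMask, target_side: int, box: FovBox) -> BrainMask:
    vol = Volume3D(mask.values.astype(np.float32), background_value=0.0)
    return BrainMask(pad_crop(vol, target_side, box).values > 0.5)


def normalize_minus1_1(volume: Volume3D) -> Volume3D:
    """Affine rescale sending the volume min to -1 and max to +1."""
    vmin = float(volume.values.min())
    vmax = float(volume.values.max())
    if vmax == vmin:
        raise ValueError("constant volume: [-1, 1] normalization undefined")
    scaled = 2.0 * (volume.values.astype(np.float64) - vmin) / (vmax - vmin) - 1.0
    bg = 2.0 * (volume.background_value - vmin) / (vmax - vmin) - 1.0
    return Volume3D(
        scaled.astype(np.float32),
        spacing=volume.spacing,
        background_value=float(bg),
        affine=volume.affine,
    )


def stack_ground_truth(gm: np.ndarray, wm: np.ndarray, csf: np.ndarray) -> TissueProbMap:
    """Stack per-tissue grids into the (3, D, H, W) training target."""
    gm, wm, csf = (np.asarray(a) for a in (gm, wm, csf))
    if not (gm.shape == wm.shape == csf.shape):
        raise ValueError("gm/wm/csf grids must share a shape")
    stacked = np.stack([gm, wm, csf])
    if stacked.min() < 0 or stacked.max() > 1:
        raise ValueError("tissue probabilities must lie in [0, 1]")
    return TissueProbMap(stacked)
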