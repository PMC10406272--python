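"""Synthetic skull-stripped T1w brain phantoms with exact tissue ground truth.

Anatomy is a deformed concentric ellipsoid: a WM core, a GM ribbon, an outer
CSF rim, and a central CSF ventricle. Hard labels are softened into partial
volume probability maps by Gaussian smoothing and in-mask renormalization.
Rendering applies T1w-like class contrast, a smooth multiplicative bias field,
and additive Gaussian noise. Every output is a pure function of (config, seed),
and repeated-scan pairs share one anatomy with independent noise/bias draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import CSF, GM, WM, BrainMask, TissueProbMap, Volume3D

__all__ = [
    "PhantomConfig",
    "PhantomSubject",
    "PhantomDataset",
    "make_anatomy",
    "render_t1w",
    "make_retest_pair",
    "make_dataset",
    "largest_remainder_split",
]


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the phantom generator.

    Geometric quantities are voxel units on a cubic ``grid_side`` grid.
    ``class_means`` is ordered (CSF, GM, WM) and must be strictly increasing
    (T1w contrast: CSF darkest, WM brightest).
    """

    grid_side: int = 64
    outer_radii: Optional[tuple[float, float, float]] = None
    shell_fractions: tuple[float, float, float] = (0.55, 0.82, 1.0)
    ventricle_radii: Optional[tuple[float, float, float]] = None
    pv_sigma: float = 1.0
    class_means: tuple[float, float, float] = (0.2, 0.55, 0.9)  # (CSF, GM, WM)
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.1
    deform_amplitude: float = 1.5
    seed: int = 0

    def resolved_outer_radii(self) -> tuple[float, float, float]:
        if self.outer_radii is not None:
            return self.outer_radii
        d = self.grid_side
        return (0.42 * d, 0.36 * d, 0.40 * d)

    def resolved_ventricle_radii(self) -> tuple[float, float, float]:
        if self.ventricle_radii is not None:
            return self.ventricle_radii
        d = self.grid_side
        return (0.10 * d, 0.08 * d, 0.09 * d)

    def validate(self) -> None:
        if self.grid_side < 8:
            raise ValueError("grid_side must be at least 8")
        csf_m, gm_m, wm_m = self.class_means
        if not (csf_m < gm_m < wm_m):
            raise ValueError("class_means must be strictly increasing (CSF < GM < WM)")
        fr = self.shell_fractions
        if len(fr) != 3 or not (0 < fr[0] < fr[1] < fr[2] <= 1.0):
            raise ValueError("shell_fractions must be strictly increasing in (0, 1]")
        if self.pv_sigma < 0:
            raise ValueError("pv_sigma must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bias_amplitude < 0 or self.bias_amplitude >= 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")
        outer = self.resolved_outer_radii()
        vent = self.resolved_ventricle_radii()
        if min(outer) <= 0:
            raise ValueError("outer_radii must be positive")
        # ventricle must sit strictly inside the WM core
        if any(v >= fr[0] * o for v, o in zip(vent, outer)):
            raise ValueError("ventricle_radii must fit inside the white-matter core")
        if max(outer) > self.grid_side / 2:
            raise ValueError("brain ellipsoid exceeds the grid")


@dataclass
class PhantomSubject:
    """One generated subject: rendered volume(s) plus shared ground truth."""

    volume: Volume3D
    probmap: TissueProbMap
    mask: BrainMask
    seed: int
    retest_volume: Optional[Volume3D] = None


@dataclass
class PhantomDataset:
    subjects: list[PhantomSubject]
    split: dict[str, list[int]] = field(default_factory=dict)

    def members(self, name: str) -> list[PhantomSubject]:
        return [self.subjects[i] for i in self.split[name]]


def _smooth_random_field(
    rng: np.random.Generator, side: int, coarse: int = 5
) -> np.ndarray:
    """A smooth field on side^3, in [-1, 1] with max |value| == 1."""
    grid = rng.standard_normal((coarse, coarse, coarse))
    zoom = side / coarse
    fine = ndimage.zoom(grid, zoom, order=3, mode="nearest", grid_mode=True)
    fine = fine[:side, :side, :side]
    peak = np.abs(fine).max()
    if peak == 0:  # pragma: no cover - measure-zero draw
        return fine
    return fine / peak


def _hard_labels(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer grid: -1 background, 0 GM, 1 WM, 2 CSF (deformed ellipsoids)."""
    d = cfg.grid_side
    center = (d - 1) / 2.0
    coords = list(np.meshgrid(*([np.arange(d, dtype=np.float64)] * 3), indexing="ij"))
    if cfg.deform_amplitude > 0:
        # one smooth displacement field per axis warps the anatomy
        for ax in range(3):
            coords[ax] = coords[ax] + cfg.deform_amplitude * _smooth_random_field(rng, d)
    outer = cfg.resolved_outer_radii()
    vent = cfg.resolved_ventricle_radii()
    r_brain = np.sqrt(sum(((c - center) / R) ** 2 for c, R in zip(coords, outer)))
    r_vent = np.sqrt(sum(((c - center) / R) ** 2 for c, R in zip(coords, vent)))

    wm_f, gm_f, brain_f = cfg.shell_fractions
    labels = np.full((d, d, d), -1, dtype=np.int8)
    labels[r_brain <= brain_f] = CSF      # outer rim
    labels[r_brain <= gm_f] = GM          # cortical ribbon
    labels[r_brain <= wm_f] = WM          # core
    labels[(r_vent <= 1.0) & (labels != -1)] = CSF  # central ventricle
    return labels


def make_anatomy(cfg: PhantomConfig) -> tuple[TissueProbMap, BrainMask]:
    """Generate ground-truth probability maps and the brain mask.

    Hard concentric labels are warped by a seeded low-frequency deformation,
    one-hot encoded, smoothed with ``pv_sigma`` and renormalized so in-mask
    channels sum to 1; out-of-mask probabilities are exactly zero.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = _hard_labels(cfg, rng)
    mask = labels != -1
    if not mask.any():
        raise ValueError("degenerate geometry: empty brain mask")

    onehot = np.zeros((3,) + labels.shape, dtype=np.float64)
    for c in (GM, WM, CSF):
        onehot[c] = labels == c

    if cfg.pv_sigma > 0:
        soft = np.stack(
            [ndimage.gaussian_filter(onehot[c], cfg.pv_sigma) for c in range(3)]
        )
    else:
        soft = onehot
    soft[:, ~mask] = 0.0
    total = soft.sum(axis=0)
    # smoothing of nonnegative mass keeps in-mask sums positive
    soft[:, mask] /= total[mask]
    probmap = TissueProbMap(soft.astype(np.float32))
    return probmap, BrainMask(mask)


def _bias_field(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.bias_amplitude == 0:
        return np.ones((cfg.grid_side,) * 3)
    return 1.0 + cfg.bias_amplitude * _smooth_random_field(rng, cfg.grid_side)


def render_t1w(
    probmap: TissueProbMap,
    mask: BrainMask,
    cfg: PhantomConfig,
    rng: Optional[np.random.Generator] = None,
) -> Volume3D:
    """Render a T1w-like volume from tissue probabilities.

    intensity = (sum_c prob_c * class_mean_c) * bias + Gaussian noise inside
    the mask; the background value (0) outside.
    """
    cfg.validate()
    if probmap.spatial_shape != mask.shape:
        raise ValueError("probability map and mask shapes differ")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    csf_m, gm_m, wm_m = cfg.class_means
    means_by_channel = np.array([gm_m, wm_m, csf_m])  # channel order GM, WM, CSF
    clean = np.tensordot(means_by_channel, probmap.values, axes=(0, 0))
    img = clean * _bias_field(cfg, rng)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    out = np.where(mask.values, img, 0.0)
    return Volume3D(out.astype(np.float32), background_value=0.0)


def make_retest_pair(
    cfg: PhantomConfig,
) -> tuple[Volume3D, Volume3D, TissueProbMap, BrainMask]:
    """One anatomy rendered twice with independent noise and bias draws."""
    probmap, mask = make_anatomy(cfg)
    child_a, child_b = np.random.SeedSequence(cfg.seed).spawn(2)
    vol_a = render_t1w(probmap, mask, cfg, rng=np.random.default_rng(child_a))
    vol_b = render_t1w(probmap, mask, cfg, rng=np.random.default_rng(child_b))
    return vol_a, vol_b, probmap, mask


def largest_remainder_split(n: int, ratio: Sequence[int]) -> tuple[int, ...]:
    """Apportion n items to ratio parts by largest-remainder rounding."""
    ratio = tuple(ratio)
    if n < 0 or any(r <= 0 for r in ratio):
        raise ValueError("n must be >= 0 and ratio parts positive")
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    leftover = n - sum(sizes)
    # ties broken toward earlier parts (stable sort on -remainder)
    order = sorted(range(len(ratio)), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        sizes[i] += 1
    return tuple(sizes)


def make_dataset(
    cfg: PhantomConfig,
    n: int,
    ratio: Sequence[int] = (3, 1, 1),
    retest: bool = False,
) -> PhantomDataset:
    """Generate n subjects with distinct anatomy seeds and a 3:1:1-style split.

    Split membership follows largest-remainder rounding of ``ratio`` over the
    subject order; splits are disjoint and exhaustive.
    """
    cfg.validate()
    if n < 3 and tuple(ratio) == (3, 1, 1):
        raise ValueError("need n >= 3 subjects for a 3:1:1 split")
    if n < 1:
        raise ValueError("n must be >= 1")
    sizes = largest_remainder_split(n, ratio)
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(cfg.seed).spawn(n)]
    subjects = []
    for s in seeds:
        sub_cfg = replace(cfg, seed=s)
        if retest:
            vol_a, vol_b, probmap, mask = make_retest_pair(sub_cfg)
            subjects.append(PhantomSubject(vol_a, probmap, mask, s, retest_volume=vol_b))
        else:
            probmap, mask = make_anatomy(sub_cfg)
            vol = render_t1w(probmap, mask, sub_cfg)
            subjects.append(PhantomSubject(vol, probmap, mask, s))
    idx = list(range(n))
    split = {
        "train": idx[: sizes[0]],
        "val": idx[sizes[0] : sizes[0] + sizes[1]],
        "test": idx[sizes[0] + sizes[1] :],
    }
    return PhantomDataset(subjects, split)
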