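import math

import numpy as np
import pytest

from tabseg import metrics as M
from tabseg.types import BrainMask, TissueProbMap


# ---- independent brute-force oracles ---------------------------------------
def oracle_dice(a, b):
    inter = np.sum(a & b)
    denom = np.sum(a) + np.sum(b)
    return 1.0 if denom == 0 else 2.0 * inter / denom


def oracle_jaccard(a, b):
    union = np.sum(a | b)
    return 1.0 if union == 0 else np.sum(a & b) / union


def oracle_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)):
    pa = np.argwhere(a) * np.asarray(spacing)
    pb = np.argwhere(b) * np.asarray(spacing)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
    return math.sqrt(max(d2.min(axis=1).max(), d2.min(axis=0).max()))


def oracle_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))


def oracle_rank(v):
    """Average ranks, from first principles."""
    v = np.asarray(v, float)
    ranks = np.empty(v.size)
    for i, x in enumerate(v):
        less = np.sum(v < x)
        equal = np.sum(v == x)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def oracle_spearman(x, y):
    return oracle_pearson(oracle_rank(x), oracle_rank(y))


def random_mask_pair(rng, side=8, p=0.3):
    a = rng.random((side,) * 3) < p
    b = rng.random((side,) * 3) < p
    return a, b


# ---- unit examples ---------------------------------------------------------
def test_brain_restrict_examples(rng):
    vals = rng.random((3, 4, 4, 4)).astype(np.float32)
    pm = TissueProbMap(vals)
    mask = np.zeros((4, 4, 4), bool)
    mask[0, 0, :5] = True
    mask[1, 2, 3] = True
    out = M.brain_restrict(pm, BrainMask(mask), 1)
    assert out.shape == (5,)
    # triple-loop extraction oracle
    expected = [vals[1, i, j, k] for i in range(4) for j in range(4) for k in range(4)
                if mask[i, j, k]]
    assert np.array_equal(out, expected)
    full = M.brain_restrict(pm, BrainMask(np.ones((4, 4, 4), bool)), 0)
    assert full.shape == (64,)
    with pytest.raises(ValueError):
        M.brain_restrict(pm, BrainMask(np.zeros((4, 4, 4), bool)), 0)


def test_argmax_segmentation_and_ties(rng):
    vals = np.zeros((3, 2, 2, 2), np.float32)
    vals[1, 0, 0, 0] = 1.0                      # one-hot WM
    vals[:, 0, 0, 1] = 1.0 / 3.0                # exact three-way tie
    mask = np.ones((2, 2, 2), bool)
    mask[1, 1, 1] = False
    seg = M.argmax_segmentation(TissueProbMap(vals), BrainMask(mask))
    assert seg.labels[0, 0, 0] == 1
    assert seg.labels[0, 0, 1] == 0             # tie -> lowest channel (GM)
    assert seg.labels[1, 1, 1] == -1
    # random maps equal a per-voxel brute-force max search
    vals = rng.random((3, 4, 4, 4)).astype(np.float32)
    seg = M.argmax_segmentation(TissueProbMap(vals), BrainMask(np.ones((4, 4, 4), bool)))
    for i in range(4):
        for j in range(4):
            for k in range(4):
                best = max(range(3), key=lambda c: (vals[c, i, j, k], -c))
                assert seg.labels[i, j, k] == best


def test_binary_tissue_map_partition():
    labels = np.full((3, 3, 3), -1, np.int8)
    labels[1, :, :] = 0
    labels[2, 0, :] = 2
    from tabseg.types import SegmentationMask

    seg = SegmentationMask(labels)
    gm = M.binary_tissue_map(seg, 0)
    wm = M.binary_tissue_map(seg, 1)
    csf = M.binary_tissue_map(seg, 2)
    assert gm.sum() == 9 and wm.sum() == 0 and csf.sum() == 3
    assert np.array_equal(gm | wm | csf, labels != -1)


def test_dice_jaccard_examples():
    a = np.zeros((3, 3, 3), bool)
    b = np.zeros((3, 3, 3), bool)
    a.ravel()[:4] = True
    b.ravel()[1:7] = True  # |A|=4, |B|=6, |A∩B|=3
    assert M.dice(a, b) == pytest.approx(0.6)
    assert M.jaccard(a, b) == pytest.approx(3 / 7)
    assert M.dice(a, a) == 1.0
    assert M.jaccard(b, b) == 1.0
    disjoint = np.zeros_like(a)
    disjoint.ravel()[-3:] = True
    assert M.dice(a, disjoint) == 0.0
    assert M.jaccard(a, disjoint) == 0.0
    empty = np.zeros_like(a)
    assert M.dice(empty, empty) == 1.0
    assert M.jaccard(empty, empty) == 1.0


def test_hausdorff_examples():
    a = np.zeros((5, 5, 5), bool)
    b = np.zeros((5, 5, 5), bool)
    a[0, 0, 0] = True
    b[3, 0, 0] = True
    assert M.hausdorff(a, b) == pytest.approx(3.0)
    assert M.hausdorff(a, a) == 0.0
    with pytest.raises(ValueError):
        M.hausdorff(a, np.zeros_like(a))
    # anisotropic spacing is honored
    assert M.hausdorff(a, b, spacing=(2.0, 1.0, 1.0)) == pytest.approx(6.0)


def test_pearson_spearman_examples():
    x = np.array([0.0, 0.5, 1.0])
    y = np.array([0.1, 0.4, 0.9])
    assert M.pearson(x, x) == pytest.approx(1.0)
    assert M.pearson(x, -x) == pytest.approx(-1.0)
    assert M.pearson(x, y) == pytest.approx(oracle_pearson(x, y), abs=1e-12)
    assert M.spearman(x, np.exp(x)) == pytest.approx(1.0)       # monotone transform
    assert M.spearman(x, -(x ** 3)) == pytest.approx(-1.0)      # order reversal
    with_ties = (np.array([1, 2, 2, 3, 4.0]), np.array([2, 1, 4, 4, 5.0]))
    assert M.spearman(*with_ties) == pytest.approx(oracle_spearman(*with_ties), abs=1e-12)
    with pytest.raises(ValueError):
        M.pearson(np.ones(5), x.repeat(2)[:5])
    with pytest.raises(ValueError):
        M.spearman(np.ones(5), np.arange(5.0))


def test_mse_map_examples(rng):
    x = rng.random(50)
    assert M.mse_map(x, x) == 0.0
    assert M.mse_map(x + 0.3, x) == pytest.approx(0.09)
    y = rng.random(50)
    assert M.mse_map(x, y) == pytest.approx(sum((a - b) ** 2 for a, b in zip(x, y)) / 50)
    with pytest.raises(ValueError):
        M.mse_map(x, y[:-1])


# ---- oracle equivalence sweep ----------------------------------------------
def test_binary_metrics_match_oracles_100_trials():
    rng = np.random.default_rng(99)
    checked_hd = 0
    for _ in range(100):
        a, b = random_mask_pair(rng)
        d = M.dice(a, b)
        j = M.jaccard(a, b)
        assert abs(d - oracle_dice(a, b)) < 1e-9
        assert abs(j - oracle_jaccard(a, b)) < 1e-9
        assert abs(d - 2 * j / (1 + j)) < 1e-9
        assert abs(M.dice(b, a) - d) < 1e-9          # symmetry
        assert abs(M.jaccard(b, a) - j) < 1e-9
        if a.any() and b.any():
            hd = M.hausdorff(a, b)
            assert abs(hd - oracle_hausdorff(a, b)) < 1e-9
            assert abs(M.hausdorff(b, a) - hd) < 1e-9
            checked_hd += 1
    assert checked_hd >= 90


def test_continuous_metrics_match_oracles_100_trials():
    rng = np.random.default_rng(77)
    for _ in range(100):
        x = rng.random(64)
        y = rng.random(64)
        assert abs(M.pearson(x, y) - oracle_pearson(x, y)) < 1e-9
        assert abs(M.spearman(x, y) - oracle_spearman(x, y)) < 1e-9
        assert abs(M.mse_map(x, y) - np.mean((x - y) ** 2)) < 1e-9


# ---- evaluate --------------------------------------------------------------
def _random_probmap(rng, side=8):
    logits = rng.standard_normal((3, side, side, side))
    e = np.exp(logits)
    probs = e / e.sum(axis=0)
    return TissueProbMap(probs.astype(np.float32))


def test_evaluate_perfect_agreement(rng):
    gt = _random_probmap(rng)
    mask = BrainMask(np.ones((8, 8, 8), bool))
    rec = M.evaluate(gt, gt, mask)
    for tissue in range(3):
        tm = rec.for_tissue(tissue)
        assert tm.dice == 1.0
        assert tm.jaccard == 1.0
        assert tm.pearson == pytest.approx(1.0)
        assert tm.spearman == pytest.approx(1.0)
        assert tm.hausdorff == 0.0
        assert tm.mse == 0.0


def test_evaluate_uniform_prediction_raises(rng):
    gt = _random_probmap(rng)
    uniform = TissueProbMap(np.full((3, 8, 8, 8), 1.0 / 3.0, np.float32))
    mask = BrainMask(np.ones((8, 8, 8), bool))
    with pytest.raises(ValueError):
        M.evaluate(uniform, gt, mask)


def test_evaluate_matches_component_calls(rng):
    pred = _random_probmap(rng, side=16)
    gt = _random_probmap(rng, side=16)
    mask = BrainMask(rng.random((16, 16, 16)) < 0.8)
    rec = M.evaluate(pred, gt, mask)
    seg_p = M.argmax_segmentation(pred, mask)
    seg_g = M.argmax_segmentation(gt, mask)
    for tissue in range(3):
        tm = rec.for_tissue(tissue)
        xv = M.brain_restrict(pred, mask, tissue)
        yv = M.brain_restrict(gt, mask, tissue)
        bp = M.binary_tissue_map(seg_p, tissue)
        bg = M.binary_tissue_map(seg_g, tissue)
        assert tm.dice == M.dice(bp, bg)
        assert tm.jaccard == M.jaccard(bp, bg)
        assert tm.pearson == M.pearson(xv, yv)
        assert tm.spearman == M.spearman(xv, yv)
        assert tm.mse == M.mse_map(xv, yv)
        assert tm.hausdorff == M.hausdorff(bp, bg)


def test_metrics_ignore_out_of_mask_voxels(rng):
    pred = _random_probmap(rng)
    gt = _random_probmap(rng)
    mask_arr = rng.random((8, 8, 8)) < 0.7
    mask = BrainMask(mask_arr)
    rec1 = M.evaluate(pred, gt, mask)
    # scribble on out-of-mask voxels: results must not move
    noisy = pred.values.copy()
    noisy[:, ~mask_arr] = rng.random((3, int((~mask_arr).sum()))).astype(np.float32)
    rec2 = M.evaluate(TissueProbMap(noisy), gt, mask)
    assert rec1.to_flat_dict() == rec2.to_flat_dict()


def test_metrics_record_flat_round_trip(rng):
    pred = _random_probmap(rng)
    gt = _random_probmap(rng)
    mask = BrainMask(np.ones((8, 8, 8), bool))
    rec = M.evaluate(pred, gt, mask)
    flat = rec.to_flat_dict()
    assert len(flat) == 18
    from tabseg.types import MetricsRecord

    assert MetricsRecord.from_flat_dict(flat).to_flat_dict() == flat
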