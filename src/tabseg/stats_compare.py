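"""Paired model comparison (Wilcoxon signed-rank with star annotations) and
the test-retest reliability protocol.

The signed-rank test drops zero differences, assigns average ranks to tied
absolute differences, and is two-sided. For n <= 25 informative pairs the
p-value comes from the exact null distribution (sign-flip enumeration,
realized as a generating-function convolution over doubled ranks, which is
identical to enumerating all 2^n sign assignments); beyond that a normal
approximation with tie correction and continuity correction is used.
No multiple-testing correction is applied by default, matching how raw
pairwise stars are usually reported; Holm adjustment is available via a flag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import metrics as M
from .types import TISSUES, BrainMask, MetricsRecord, TissueProbMap

__all__ = [
    "wilcoxon_signed_rank",
    "stars",
    "PairedComparison",
    "compare_models",
    "retest_similarity",
    "holm_adjust",
]

EXACT_N_MAX = 25
METRIC_NAMES = ("dice", "jaccard", "pearson", "spearman", "hausdorff", "mse")


def _exact_wplus_counts(double_ranks: np.ndarray) -> np.ndarray:
    """counts[w] = number of sign assignments with 2*W+ == w."""
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided paired signed-rank test. Returns (statistic, p_value).

    The statistic is min(W+, W-), symmetric under argument swap.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("no informative pairs (all differences are zero)")
    ranks = sstats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= EXACT_N_MAX:
        dbl = np.rint(2.0 * ranks).astype(np.int64)
        counts = _exact_wplus_counts(dbl)
        total = counts.sum()  # == 2^n
        w2 = int(round(2.0 * w_plus))
        p_low = counts[: w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= ((tie_counts ** 3 - tie_counts).sum()) / 48.0
        if var <= 0:
            raise ValueError("degenerate variance in normal approximation")
        dev = w_plus - mean
        correction = 0.5 * np.sign(dev)
        z = (dev - correction) / math.sqrt(var)
        p = float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))
    return statistic, p


def stars(p: float) -> str:
    """Significance ladder: ns, * (<0.05), ** (<0.01), *** (<0.001), **** (<0.0001)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class PairedComparison:
    metric: str
    tissue: str
    values_a: list[float] = field(repr=False, default_factory=list)
    values_b: list[float] = field(repr=False, default_factory=list)
    statistic: float = math.nan
    p_value: float = math.nan
    stars: str = "ns"
    degenerate: bool = False

    def annotation(self) -> str:
        return "ns (degenerate)" if self.degenerate else self.stars


def compare_models(
    records_a: list[MetricsRecord],
    records_b: list[MetricsRecord],
    holm: bool = False,
) -> list[PairedComparison]:
    """One two-sided signed-rank comparison per (metric, tissue): 18 tests."""
    if len(records_a) != len(records_b):
        raise ValueError("record lists must pair the same subjects")
    if not records_a:
        raise ValueError("no records to compare")
    comparisons = []
    for metric in METRIC_NAMES:
        for t, tissue in enumerate(TISSUES):
            va = [getattr(r.for_tissue(t), metric) for r in records_a]
            vb = [getattr(r.for_tissue(t), metric) for r in records_b]
            comp = PairedComparison(metric=metric, tissue=tissue,
                                    values_a=va, values_b=vb)
            try:
                comp.statistic, comp.p_value = wilcoxon_signed_rank(va, vb)
                comp.stars = stars(comp.p_value)
            except ValueError:
                comp.degenerate = True
                comp.stars = "ns"
            comparisons.append(comp)
    if holm:
        ps = [c.p_value for c in comparisons if not c.degenerate]
        adjusted = iter(holm_adjust(ps))
        for c in comparisons:
            if not c.degenerate:
                c.p_value = next(adjusted)
                c.stars = stars(c.p_value)
    return comparisons


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment, preserving input order."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def retest_similarity(
    pred_a: TissueProbMap,
    pred_b: TissueProbMap,
    mask: BrainMask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> MetricsRecord:
    """Agreement between two outputs on repeated scans of one subject.

    Identical computation to `metrics.evaluate` with the second prediction
    playing the reference role — it quantifies agreement, not accuracy.
    """
    return M.evaluate(pred_a, pred_b, mask, spacing=spacing)
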