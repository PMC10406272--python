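"""Plain box-plot reporting of per-subject metrics with star annotations.

Faithful journal styling is a non-goal; this renders one panel per tissue for
a chosen metric, one box per model, and annotates each non-reference model
with the significance stars of its paired comparison against the reference
(first) model.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .stats_compare import wilcoxon_signed_rank, stars as p_stars
from .types import TISSUES, MetricsRecord

__all__ = ["metric_boxplot"]


def metric_boxplot(
    records_by_model: dict[str, list[MetricsRecord]],
    metric: str,
    out_path: Union[str, Path],
) -> Path:
    """Write a 3-panel (GM/WM/CSF) box plot of one metric across models."""
    if not records_by_model:
        raise ValueError("no models given")
    model_names = list(records_by_model)
    reference = model_names[0]
    fig, axes = plt.subplots(1, 3, figsize=(4 * 3, 4), sharey=True)
    for t, (ax, tissue) in enumerate(zip(axes, TISSUES)):
        data = [
            [getattr(r.for_tissue(t), metric) for r in records_by_model[name]]
            for name in model_names
        ]
        ax.boxplot(data, tick_labels=model_names)
        ax.set_title(tissue)
        ax.tick_params(axis="x", rotation=45)
        top = max(max(d) for d in data if d)
        for i, name in enumerate(model_names[1:], start=1):
            try:
                _, p = wilcoxon_signed_rank(data[0], data[i])
                label = p_stars(p)
            except ValueError:
                label = "ns"
            ax.text(i + 1, top, label, ha="center", va="bottom", fontsize=9)
    axes[0].set_ylabel(metric)
    fig.suptitle(f"{metric} (reference: {reference})")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
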