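"""Small plotting helpers (accuracy scatter, difference histogram, pies)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import AccuracyVector, AdvantageResult

__all__ = ["accuracy_scatter", "difference_histogram", "best_encoded_pie"]


def accuracy_scatter(acc_a: AccuracyVector, acc_b: AccuracyVector, labels=("A", "B"), ax=None):
    """Per-voxel accuracy of model A vs model B with validity threshold lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    both = acc_a.valid & acc_b.valid
    a_wins = both & (acc_a.rho > acc_b.rho)
    neither = ~(acc_a.valid | acc_b.valid)
    ax.scatter(acc_a.rho[neither], acc_b.rho[neither], s=4, c="k", alpha=0.3)
    ax.scatter(acc_a.rho[a_wins], acc_b.rho[a_wins], s=4, c="purple")
    ax.scatter(acc_a.rho[both & ~a_wins], acc_b.rho[both & ~a_wins], s=4, c="green")
    thr = acc_a.threshold
    ax.axvline(thr, ls="--", c="tab:blue", lw=0.8)
    ax.axhline(thr, ls="--", c="tab:blue", lw=0.8)
    ax.plot([-1, 1], [-1, 1], c="gray", lw=0.5)
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    return ax


def difference_histogram(result: AdvantageResult, ax=None):
    """Histogram of per-voxel accuracy differences (A minus B)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    widths = np.diff(result.hist_edges)
    ax.bar(result.hist_edges[:-1], result.hist_counts, width=widths, align="edge")
    ax.axvline(0, c="k", lw=0.8)
    ax.set_xlabel(f"rho({result.label_a}) - rho({result.label_b})")
    ax.set_ylabel("voxels")
    ax.set_title(f"{result.label_a}: {100 * result.prop_a:.1f}%")
    return ax


def best_encoded_pie(proportions: dict[str, float], ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    ax.pie(list(proportions.values()), labels=list(proportions), autopct="%1.0f%%")
    return ax
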