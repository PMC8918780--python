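"""Figure panels: violin, cumulative-frequency, scatter and histogram plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "plot_violin",
    "plot_cumulative",
    "plot_scatter_groups",
    "plot_diameter_histogram",
]


def _save(fig, path) -> Path:
    path = Path(path)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return path


def plot_violin(values_by_group: dict, ylabel: str, path) -> Path:
    fig, ax = plt.subplots(figsize=(1.2 * len(values_by_group) + 1.5, 3.2))
    data = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(data) + 1), list(values_by_group))
    ax.set_ylabel(ylabel)
    return _save(fig, path)


def plot_cumulative(curves: dict[str, pd.DataFrame], path, first_layer: float = 7.5) -> Path:
    """Cumulative frequency of distance to the reference per population."""
    fig, ax = plt.subplots(figsize=(4, 3.2))
    for name, curve in curves.items():
        ax.step(curve["distance"], curve["cumulative_pct"], where="post", label=name)
    ax.axvline(first_layer, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("distance from epithelium (µm)")
    ax.set_ylabel("cumulative frequency (%)")
    ax.set_ylim(0, 102)
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)


def plot_scatter_groups(values_by_group: dict, ylabel: str, path) -> Path:
    fig, ax = plt.subplots(figsize=(1.2 * len(values_by_group) + 1.5, 3.2))
    rng = np.random.default_rng(0)
    for i, (name, vals) in enumerate(values_by_group.items()):
        vals = np.asarray(vals, dtype=float)
        ax.scatter(i + rng.uniform(-0.12, 0.12, len(vals)), vals, s=14, alpha=0.8)
        ax.hlines(np.median(vals), i - 0.2, i + 0.2, color="k", lw=1.2)
    ax.set_xticks(range(len(values_by_group)), list(values_by_group))
    ax.set_ylabel(ylabel)
    return _save(fig, path)


def plot_diameter_histogram(hist: pd.DataFrame, path) -> Path:
    fig, ax = plt.subplots(figsize=(4, 3.2))
    width = hist["bin_right"] - hist["bin_left"]
    ax.bar(hist["bin_left"], hist["frequency_pct"], width=width, align="edge", edgecolor="k", lw=0.4)
    ax.set_xlabel("vessel diameter (µm)")
    ax.set_ylabel("relative frequency (%)")
    return _save(fig, path)
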