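"""Figure helpers: elbow curve, ordination scatter and the SOM glyph grid."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .som import MEASURE_COLUMNS, BinSummary, SOMModel

__all__ = ["plot_wss_curve", "plot_pcoa", "plot_som_grid", "plot_heatmap"]

_RING = {
    "control": "green", "pure-BPS": "purple", "pure-NUPP": "blue",
    "pure-MFP": "orange", "mixed": "cyan", "global": "magenta", "empty": "lightgray",
}
_SLICE = {"bps_measure": "purple", "nupp_measure": "blue", "mfp_measure": "orange"}


def plot_wss_curve(curve, path=None, ax=None):
    ks = [k for k, _ in curve]
    wss = [w for _, w in curve]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(ks, wss, "o-")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("within-cluster sum of squares")
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_pcoa(coords: pd.DataFrame, labels=None, path=None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    c = None if labels is None else pd.factorize(np.asarray(labels))[0]
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], c=c, cmap="tab10", s=18)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_heatmap(grid: np.ndarray, path=None, ax=None, cmap="Greens", annot=False):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    im = ax.imshow(grid, cmap=cmap)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if annot:
        for (i, j), v in np.ndenumerate(grid):
            ax.text(j, i, f"{v:.0f}", ha="center", va="center", fontsize=8)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_som_grid(model: SOMModel, bins: BinSummary, path=None):
    """Pie-glyph grid: slice sizes are bin-mean measures, ring colour the
    purity label."""
    rows, cols = model.config.rows, model.config.cols
    fig, axes = plt.subplots(rows, cols, figsize=(1.3 * cols, 1.3 * rows),
                             subplot_kw={"aspect": "equal"})
    for _, rec in bins.table.iterrows():
        ax = axes[int(rec["row"]), int(rec["col"])]
        sizes = [max(rec[f"mean_{c}"], 1e-9) for c in MEASURE_COLUMNS]
        ax.pie(sizes, colors=[_SLICE[c] for c in MEASURE_COLUMNS],
               radius=0.9, wedgeprops={"linewidth": 0})
        ring = plt.Circle((0, 0), 1.0, fill=False, lw=2.5,
                          color=_RING.get(rec["label"], "gray"))
        ax.add_patch(ring)
        ax.set_title(str(int(rec["count"])), fontsize=7)
        ax.set_xticks([]), ax.set_yticks([])
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
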