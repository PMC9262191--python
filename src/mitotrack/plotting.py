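"""Figure rendering for temporally aligned single-cell features.

All temporal plots share the three-segment aligned axis (interphase,
stretched IP-MA block, post-MA) with vertical anchor lines at the IP and MA
transitions.  Grouping modes mirror typical experiment layouts: one pooled
plot, one subplot per group, or combined lines with error bars in a single
axis for direct comparison.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")  # headless rendering; figures are written to files
import matplotlib.pyplot as plt

PLOT_KINDS = ("heatmap", "mean_sd", "combined_lines", "violin", "box",
              "histogram")
TEMPORAL_KINDS = ("heatmap", "mean_sd", "combined_lines")


def _anchor_lines(ax, anchors) -> None:
    if anchors is None:
        return
    for pos in anchors:
        ax.axvline(pos, color="k", linestyle="--", linewidth=0.8)


def render_plot(kind: str, data: dict[str, np.ndarray], out_path,
                anchors: tuple[int, int] | None = None,
                mode: str = "combined", title: str = "",
                errorbar: str = "sd") -> Path:
    """Render one figure and write it as PNG.

    ``data`` maps group names to arrays: ``(n_cells, T)`` aligned matrices
    for temporal kinds, 1D value vectors for distribution kinds.  Temporal
    kinds require the aligned axis with its (IP, MA) ``anchors``.  ``mode``
    is ``combined`` (single axis) or ``subplots`` (one per group);
    ``errorbar`` chooses the band: one standard deviation (default) or
    ``sem``.
    """
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind '{kind}'; use one of {PLOT_KINDS}")
    if not data:
        raise ValueError("no data to plot")
    if kind in TEMPORAL_KINDS and anchors is None:
        raise ValueError(f"temporal plot '{kind}' requires synchronized "
                         "cells and their (IP, MA) anchors")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    if kind == "heatmap":
        fig, axes = _axes_grid(len(data))
        for ax, (name, mat) in zip(axes, data.items()):
            mat = np.atleast_2d(np.asarray(mat, float))
            ax.imshow(mat, aspect="auto", interpolation="nearest")
            _anchor_lines(ax, anchors)
            ax.set_title(f"{name} (n={mat.shape[0]})")
            ax.set_xlabel("aligned frame")
            ax.set_ylabel("cell")
    elif kind in ("mean_sd", "combined_lines"):
        if mode == "subplots" and kind == "mean_sd":
            fig, axes = _axes_grid(len(data))
            for ax, (name, mat) in zip(axes, data.items()):
                _mean_band(ax, name, mat, errorbar)
                _anchor_lines(ax, anchors)
                ax.set_title(name)
        else:
            fig, ax = plt.subplots(figsize=(6.4, 4.0))
            for name, mat in data.items():
                _mean_band(ax, name, mat, errorbar)
            _anchor_lines(ax, anchors)
            ax.legend(fontsize=8)
            axes = [ax]
    elif kind in ("violin", "box"):
        fig, ax = plt.subplots(figsize=(6.4, 4.0))
        names = list(data)
        vals = [np.asarray(data[n], float)[np.isfinite(np.asarray(data[n], float))]
                for n in names]
        if kind == "violin":
            ax.violinplot(vals, showmedians=True)
        else:
            ax.boxplot(vals)
        ax.set_xticks(range(1, len(names) + 1), names)
        axes = [ax]
    else:  # histogram
        fig, ax = plt.subplots(figsize=(6.4, 4.0))
        for name, vals in data.items():
            vals = np.asarray(vals, float)
            ax.hist(vals[np.isfinite(vals)], bins=20, alpha=0.6, label=name)
        ax.legend(fontsize=8)
        axes = [ax]
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def _axes_grid(n: int):
    cols = min(3, n)
    rows = math.ceil(n / cols)
    fig, axes = plt.subplots(rows, cols, figsize=(4.8 * cols, 3.4 * rows),
                             squeeze=False)
    flat = axes.ravel()
    for ax in flat[n:]:
        ax.set_visible(False)
    return fig, list(flat[:n])


def _mean_band(ax, name: str, mat: np.ndarray, errorbar: str) -> None:
    mat = np.atleast_2d(np.asarray(mat, float))
    mean = np.nanmean(mat, axis=0)
    spread = np.nanstd(mat, axis=0)
    if errorbar == "sem":
        n = np.maximum(np.sum(np.isfinite(mat), axis=0), 1)
        spread = spread / np.sqrt(n)
    t = np.arange(mat.shape[1])
    ax.plot(t, mean, label=name)
    ax.fill_between(t, mean - spread, mean + spread, alpha=0.25)
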