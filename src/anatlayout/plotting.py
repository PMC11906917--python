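"""Matplotlib rendering of layouts, topographies and comparison curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import interpolate_topo
from .projection import Layout2D


def draw_head_outline(ax, radius: float = 1.0) -> None:
    theta = np.linspace(0.0, 2.0 * np.pi, 256)
    ax.plot(radius * np.cos(theta), radius * np.sin(theta), color="k", lw=1.2)
    # nose at 90 deg (top), ears at 0/180
    nose = np.array([[-0.09, 0.995], [0.0, 1.12], [0.09, 0.995]]) * radius
    ax.plot(nose[:, 0], nose[:, 1], color="k", lw=1.2)
    for sign in (-1.0, 1.0):
        t = np.linspace(-0.35, 0.35, 64)
        ax.plot(
            sign * radius * (1.0 + 0.04 * np.cos(t * np.pi / 0.7)),
            radius * 0.25 * np.sin(t * np.pi / 0.35) * 0.45,
            color="k",
            lw=1.0,
        )


def plot_layout(
    layout: Layout2D,
    values=None,
    ax=None,
    resolution: int = 67,
    show_labels: bool = False,
):
    """Channel dots on the head outline, optionally over an interpolated field."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if values is not None:
        img = interpolate_topo(layout, values, resolution=resolution)
        ax.imshow(
            img.grid,
            origin="lower",
            extent=(-img.extent, img.extent, -img.extent, img.extent),
            cmap="RdBu_r",
        )
    draw_head_outline(ax)
    xy = layout.xy
    ax.scatter(xy[:, 0], xy[:, 1], s=18, color="k", zorder=3)
    if show_labels:
        for label, ch in layout.channels.items():
            ax.annotate(label, ch.xy, fontsize=6, xytext=(2, 2), textcoords="offset points")
    lim = max(1.3, float(np.abs(xy).max()) + 0.1) if len(xy) else 1.3
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_comparison_curves(table: pd.DataFrame, out_path=None):
    """Mean-t-by-channel-count curves, one panel per subselection mode."""
    modes = sorted(table["mode"].unique())
    fig, axes = plt.subplots(1, len(modes), figsize=(5 * len(modes), 4), squeeze=False)
    for ax, mode in zip(axes[0], modes):
        sub = table[table["mode"] == mode]
        summary = sub.groupby(["method", "n_keep"])["mean_t"].mean().reset_index()
        for method, grp in summary.groupby("method"):
            grp = grp.sort_values("n_keep")
            ax.plot(grp["n_keep"], grp["mean_t"], marker="o", label=method)
        ax.set_title(mode)
        ax.set_xlabel("number of channels")
        ax.set_ylabel("mean |t|")
        ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
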