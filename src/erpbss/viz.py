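"""Figure battery: source panels, scalp topographies, layer activations.

Scalp maps are drawn on the unit head disc using radial-basis
interpolation of the electrode values from the built-in 10-20 layout;
every map gets its own colour scale, symmetric about zero, so polarity
is comparable within a map but amplitudes are not comparable across
maps.
"""

from __future__ import annotations

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.interpolate import RBFInterpolator

from .datasets import SourceSet
from .montage import channel_positions

__all__ = ["plot_topomap", "render_source_panel", "render_layer_panel"]


def plot_topomap(values, channel_names, ax=None, n_grid: int = 64, cmap="RdBu_r"):
    """Interpolated scalp topography of one per-channel value vector.

    Colour limits are symmetric about zero and set per map; a zero map
    renders uniformly at the midpoint colour.
    """
    values = np.asarray(values, dtype=float)
    pos = channel_positions(channel_names)
    if ax is None:
        _, ax = plt.subplots(figsize=(2.2, 2.2))
    lim = np.abs(values).max()
    if lim == 0:
        lim = 1.0  # flat map -> uniform midpoint colour
    gx, gy = np.meshgrid(np.linspace(-1, 1, n_grid), np.linspace(-1, 1, n_grid))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    interp = RBFInterpolator(pos, values, kernel="thin_plate_spline")
    img = interp(grid).reshape(n_grid, n_grid)
    img[gx**2 + gy**2 > 1.0] = np.nan
    ax.imshow(
        img, origin="lower", extent=(-1, 1, -1, 1), vmin=-lim, vmax=lim, cmap=cmap
    )
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=1)
    ax.add_patch(circle)
    ax.plot([-0.08, 0, 0.08], [0.995, 1.08, 0.995], color="k", lw=1)  # nose
    ax.scatter(pos[:, 0], pos[:, 1], s=3, c="k")
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def render_source_panel(
    source_set: SourceSet,
    grand_averages,
    channels_of_interest=None,
    time_vector=None,
    path=None,
):
    """One row per source: waveforms, scalp map, reconstruction overlay.

    Left: the source's per-condition waveforms.  Middle: its scalp map.
    Right: the source's projection (solid) overlaid on the grand-average
    difference waves (dashed) for the channels of interest.  A final row
    shows the full reconstruction (sum of all projections).
    """
    conds = source_set.conditions
    chans = list(channels_of_interest or source_set.channel_names[:2])
    ch_idx = []
    unknown = [c for c in chans if c not in source_set.channel_names]
    if unknown:
        raise KeyError(f"unknown channel name(s): {unknown}")
    ch_idx = [source_set.channel_names.index(c) for c in chans]
    G = np.asarray(grand_averages, dtype=float)
    n = source_set.n_sources
    if n == 0:
        warnings.warn("empty SourceSet; rendering empty figure")
        fig = plt.figure(figsize=(6, 2))
        fig.text(0.5, 0.5, "no active sources", ha="center")
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
    if time_vector is None:
        time_vector = source_set.time_vector
    t = (
        np.asarray(time_vector)
        if time_vector is not None
        else np.arange(source_set.waveforms.shape[2])
    )
    ncols = 2 + len(conds)
    fig, axes = plt.subplots(
        n + 1, ncols, figsize=(2.2 * ncols, 1.7 * (n + 1)), squeeze=False
    )
    for i in range(n):
        ax = axes[i, 0]
        for c, cond in enumerate(conds):
            ax.plot(t, source_set.waveforms[i, c], lw=0.9, label=cond)
        ax.set_ylabel(source_set.source_ids[i], fontsize=8)
        if i == 0:
            ax.legend(fontsize=5, ncol=2)
        plot_topomap(source_set.scalp_maps[i], source_set.channel_names, ax=axes[i, 1])
        for c, cond in enumerate(conds):
            ax = axes[i, 2 + c]
            proj = source_set.project(i, cond)
            for j in ch_idx:
                ax.plot(t, G[c][:, j], "--", lw=0.7, color="0.5")
                ax.plot(t, proj[:, j], lw=0.9)
            if i == 0:
                ax.set_title(cond, fontsize=8)
    # bottom row: full reconstruction per condition
    axes[n, 0].axis("off")
    axes[n, 1].axis("off")
    axes[n, 0].text(0.5, 0.5, "reconstruction", ha="center", fontsize=8)
    for c, cond in enumerate(conds):
        ax = axes[n, 2 + c]
        rec = source_set.reconstruction(cond)
        for j in ch_idx:
            ax.plot(t, G[c][:, j], "--", lw=0.7, color="0.5")
            ax.plot(t, rec[:, j], lw=0.9)
    for ax in axes.ravel():
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def render_layer_panel(results, path=None):
    """Grid of conditions x (input | hidden layers | output) activations.

    Every unit's time course is drawn in each hidden-layer panel;
    inactive last-layer units appear as flat zero traces.
    """
    tens = results.tensors
    conds = tens.conditions
    X_rep = tens.representative_inputs()
    Z = results.activations
    Yhat = results.predicted
    t = np.asarray(tens.time_vector)
    M = len(Z)
    ncols = M + 2
    fig, axes = plt.subplots(
        len(conds), ncols, figsize=(2.1 * ncols, 1.6 * len(conds)), squeeze=False
    )
    for c, cond in enumerate(conds):
        axes[c, 0].plot(t, X_rep[c], lw=0.9)
        axes[c, 0].set_ylabel(cond, fontsize=8)
        for m in range(M):
            axes[c, m + 1].plot(t, Z[m][c], lw=0.5)
        axes[c, -1].plot(t, Yhat[c], lw=0.5)
        if c == 0:
            axes[0, 0].set_title("input", fontsize=8)
            for m in range(M):
                axes[0, m + 1].set_title(f"layer {m + 1}", fontsize=8)
            axes[0, -1].set_title("output", fontsize=8)
    for ax in axes.ravel():
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
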