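"""Optional figure export: trajectory panels and signature heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .signatures import HClusterResult

__all__ = ["plot_trajectories", "signature_heatmap"]


def plot_trajectories(trajectories, path, labels=None, log_M=True):
    """One panel per population (T above, M below) for a list of
    trajectories."""
    fig, (ax_t, ax_m) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for i, traj in enumerate(trajectories):
        label = labels[i] if labels else None
        ax_t.plot(traj.times, traj.T, lw=0.8, label=label)
        ax_m.plot(traj.times, np.maximum(traj.M, 1e-12), lw=0.8)
    ax_t.set_ylabel("T (n.u.)")
    ax_m.set_ylabel("M (n.u.)")
    ax_m.set_xlabel("time (days)")
    if log_M:
        ax_m.set_yscale("log")
    if labels:
        ax_t.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def signature_heatmap(normalized: pd.DataFrame, clustering: HClusterResult, path):
    """Red/cyan diverging heat map of normalized values in optimal leaf
    order (red = high, cyan = low)."""
    ordered = clustering.ordered(normalized)
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="cool_r",
                   vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="normalized log10 value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
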