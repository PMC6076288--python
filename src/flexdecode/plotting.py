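"""Minimal figure helpers: barcode strips and 3-D trajectory exports."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from flexdecode.characterize import Barcode
from flexdecode.geometry import Trajectory

__all__ = ["plot_barcodes", "plot_trajectories"]


def plot_barcodes(barcodes: dict[str, Barcode], path=None):
    """Black/white strip per condition: white = labeled, black = not."""
    names = list(barcodes)
    mat = np.vstack([barcodes[n].labels for n in names]).astype(float)
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(names) + 1))
    ax.imshow(mat, cmap="gray", aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("neuron (fixed order)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trajectories(trajectories: Sequence[Trajectory], path=None):
    """3-D line per condition through the projected 50 ms bins."""
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for t in trajectories:
        p = t.points
        zs = p[:, 2] if p.shape[1] > 2 else np.zeros(len(p))
        ax.plot(p[:, 0], p[:, 1], zs, label=t.condition, linewidth=1.0)
    ax.set_xlabel("c1")
    ax.set_ylabel("c2")
    ax.set_zlabel("c3")
    ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
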