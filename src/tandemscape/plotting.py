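"""Matplotlib views of the pipeline's headline outputs.

Kept deliberately small: an LD heatmap ordered 5'->3' with VNTR tracks
starred, and a two-panel G4 coverage/count profile.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .popgen import LDMatrix


def plot_ld_heatmap(ld: LDMatrix, vntr_labels: list[str] | None = None, ax=None):
    """r^2 heatmap (white = low, red = high); missing values grey,
    VNTR rows/columns marked with an asterisk."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("Reds").copy()
    cmap.set_bad("#999999")
    masked = np.ma.masked_invalid(ld.r2)
    im = ax.imshow(masked, cmap=cmap, vmin=0, vmax=1, interpolation="nearest")
    vntr_labels = set(vntr_labels or [])
    ticklabels = [f"{l}*" if l in vntr_labels else l for l in ld.labels]
    ax.set_xticks(range(len(ld.labels)))
    ax.set_yticks(range(len(ld.labels)))
    ax.set_xticklabels(ticklabels, rotation=90, fontsize=5)
    ax.set_yticklabels(ticklabels, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="$r^2$")
    return ax


def plot_g4_profile(profile, axes=None):
    """Coverage percent and hit count per bin, as in a windowed G4 scan."""
    if axes is None:
        _, axes = plt.subplots(2, 1, figsize=(8, 4), sharex=True)
    x = (profile["bin_start"] + profile["bin_end"]) / 2
    axes[0].fill_between(x, profile["coverage_percent"], step="mid", alpha=0.6)
    axes[0].axhline(50, color="grey", ls="--", lw=0.8)
    axes[0].set_ylabel("G4 coverage (%)")
    axes[1].step(x, profile["hit_count"], where="mid")
    axes[1].set_ylabel("G4 count")
    axes[1].set_xlabel("gene position (bp)")
    return axes
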