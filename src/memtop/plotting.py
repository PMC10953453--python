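"""Optional figures: per-site fragmentation bar plot with topology overlay
and the amino-acid-pair propensity heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sitestats import SiteProfile
from .topology import Topology

__all__ = ["plot_site_profile", "plot_pair_heatmap"]

_KIND_COLOR = {
    "tm_helix": "#f2c744",
    "loop_periplasmic": "#bbbbbb",
    "loop_cytosolic": "#dddddd",
    "loop_extracellular": "#bbbbbb",
    "terminus": "#eeeeee",
}


def plot_site_profile(
    profile: SiteProfile, topo: Topology | None, path: str | Path
) -> None:
    """Bar plot of summed normalized intensity per cleavage site; bar colour
    encodes the weighted average charge, with helix boxes overlaid."""
    sites = np.arange(1, profile.sequence_length)
    vals = profile.total_norm_intensity
    charges = np.nan_to_num(profile.weighted_avg_charge, nan=0.0)
    fig, ax = plt.subplots(figsize=(10, 3))
    vmax = charges.max() if charges.max() > 0 else 1.0
    colors = plt.cm.Blues(0.25 + 0.75 * charges / vmax)
    ax.bar(sites, vals, width=1.0, color=colors)
    if topo is not None:
        ymax = vals.max() if vals.max() > 0 else 1.0
        for d in topo.domains:
            if d.kind == "tm_helix":
                ax.axvspan(d.start, d.end, color=_KIND_COLOR[d.kind], alpha=0.3)
                ax.text((d.start + d.end) / 2, ymax * 1.02, d.label,
                        ha="center", fontsize=7)
    ax.set_xlabel("cleavage site (residue number)")
    ax.set_ylabel("summed normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pair_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    """20x20 heatmap of relative cleavage abundance at bond X|Y."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    ax.set_xlabel("C-terminal residue of cleaved bond")
    ax.set_ylabel("N-terminal residue of cleaved bond")
    fig.colorbar(im, ax=ax, label="relative abundance (max = 100)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
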