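"""Optional matplotlib figures for ratio histograms and library PCA."""

from __future__ import annotations

import numpy as np

from .ratiostats import RatioProfile, bin_ratios


def ratio_histogram(profile: RatioProfile, ax=None, width: float = 0.5, clamp: float = 4.0):
    """Bar plot of binned log2 ratios, colored by sign of the bin center."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    edges, counts = bin_ratios(profile, width=width, clamp=clamp)
    centers = (edges[:-1] + edges[1:]) / 2
    colors = np.where(centers < 0, "firebrick", "black")
    ax.bar(centers, counts, width=width * 0.9, color=colors)
    ax.set_xlabel(f"log2 {profile.contrast.replace('_vs_', '/')} ratio")
    ax.set_ylabel("miRNAs")
    ax.set_title("/".join(profile.condition))
    return ax


def pca_scatter(scores, design, color_by: str = "diet", components=("PC1", "PC2"), ax=None):
    """Scatter of library PCA scores, colored by one design factor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    merged = scores.join(design.set_index("library"))
    for level, group in merged.groupby(color_by):
        ax.scatter(group[components[0]], group[components[1]], label=str(level))
    ax.set_xlabel(components[0])
    ax.set_ylabel(components[1])
    ax.legend(title=color_by)
    return ax
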