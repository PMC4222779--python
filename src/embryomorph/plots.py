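"""Figure helpers: error boxplots, regression-score scatter, vector plots.

These mirror the standard presentation of landmark-error and allometry
results; all functions return the matplotlib figure so callers can save it
in any format.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .allometry import AllometryFit, SubsetComparison
from .error_analysis import INTRA_REFERENCE_MM


def error_boxplots(
    table: pd.DataFrame,
    value: str = "distance",
    by: str = "landmark",
    hue: str = "observer",
    reference_mm: float | None = INTRA_REFERENCE_MM,
    title: str = "Intraobserver landmark placement error",
):
    """Boxplots of placement error per landmark, one box per ``hue`` level,
    with the 0.1 mm reference drawn as a dotted line."""
    groups = list(dict.fromkeys(table[by]))
    hues = list(dict.fromkeys(table[hue]))
    fig, ax = plt.subplots(figsize=(max(8, 0.5 * len(groups)), 4))
    width = 0.8 / max(len(hues), 1)
    for j, h in enumerate(hues):
        data = [
            table[(table[by] == g) & (table[hue] == h)][value].to_numpy()
            for g in groups
        ]
        positions = np.arange(len(groups)) + (j - (len(hues) - 1) / 2) * width
        ax.boxplot(
            data,
            positions=positions,
            widths=width * 0.9,
            showfliers=False,
            medianprops={"color": f"C{j}"},
        )
    if reference_mm is not None:
        ax.axhline(reference_mm, linestyle=":", color="grey")
    ax.set_xticks(np.arange(len(groups)))
    ax.set_xticklabels(groups, rotation=90)
    ax.set_xlabel(by)
    ax.set_ylabel(f"{value} (mm)")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def regression_score_plot(fit: AllometryFit, label: str = "all landmarks"):
    """Regression score vs centroid size: the linearity of this scatter
    summarises how well size predicts shape."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fit.centroid_sizes, fit.regression_scores, s=20)
    ax.set_xlabel("centroid size (mm)")
    ax.set_ylabel("regression score")
    ax.set_title(f"Shape vs size ({label}); {fit.pct_variance:.1f}% explained")
    fig.tight_layout()
    return fig


def vector_plot(
    comparison: SubsetComparison,
    subsets: Sequence[str] | None = None,
    axes: tuple[int, int] = (0, 2),
):
    """Ontogenetic displacement vectors of each subset fit, projected onto a
    coordinate plane (default x-z: rostro-caudal vs dorso-ventral), drawn
    from the all-landmark mean shape."""
    names = list(subsets) if subsets is not None else list(comparison.fits)
    ax_i, ax_j = axes
    fig, ax = plt.subplots(figsize=(6, 6))
    for c, name in enumerate(names):
        vec = comparison.vectors[name]
        ax.quiver(
            vec[["x0", "y0", "z0"][ax_i]],
            vec[["x0", "y0", "z0"][ax_j]],
            vec[["x1", "y1", "z1"][ax_i]] - vec[["x0", "y0", "z0"][ax_i]],
            vec[["x1", "y1", "z1"][ax_j]] - vec[["x0", "y0", "z0"][ax_j]],
            angles="xy",
            scale_units="xy",
            scale=1,
            color=f"C{c}",
            width=0.004,
            label=name,
        )
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    ax.set_xlabel("xyz"[ax_i] + " (shape units)")
    ax.set_ylabel("xyz"[ax_j] + " (shape units)")
    ax.set_title("Ontogenetic shape-change vectors by landmark subset")
    fig.tight_layout()
    return fig
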