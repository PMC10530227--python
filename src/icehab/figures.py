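"""Report figures: PCA correlation circle and cluster boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .pca import PCSpace

__all__ = ["plot_correlation_circle", "plot_cluster_boxplots"]

#: variables shown in the cluster boxplots; distance-to-nearest-emperor is
#: omitted because it is near-constant across regions and colonies
REPORT_COLUMNS = [c for c in FEATURE_COLUMNS if c != "dist_emperor_km"]


def plot_correlation_circle(space: PCSpace, path: str | Path, axes: tuple[int, int] = (0, 1)) -> None:
    """Variables drawn as arrows of their correlations with two PC axes."""
    i, j = axes
    # correlation of variable with score = loading * sqrt(eigenvalue)
    cx = space.loadings[:, i] * np.sqrt(space.eigenvalues[i])
    cy = space.loadings[:, j] * np.sqrt(space.eigenvalues[j])
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="grey"))
    for x, y, name in zip(cx, cy, space.var_names):
        ax.annotate("", xy=(x, y), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.text(x * 1.07, y * 1.07, name, ha="center", va="center", fontsize=8)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlim(-1.15, 1.15)
    ax.set_ylim(-1.15, 1.15)
    ax.set_xlabel(f"PC{i + 1} ({space.explained_pct[i]:.1f}%)")
    ax.set_ylabel(f"PC{j + 1} ({space.explained_pct[j]:.1f}%)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cluster_boxplots(
    scored: pd.DataFrame, path: str | Path, variables: list[str] | None = None
) -> None:
    """Per-cluster boxplots of each variable, presence vs absence.

    ``scored`` needs 'cluster' (rows already filtered to the working
    certainty threshold) and 'is_presence'.
    """
    variables = variables or [v for v in REPORT_COLUMNS if v in scored.columns]
    clusters = sorted(int(c) for c in scored["cluster"].unique() if c >= 0)
    ncol = 3
    nrow = int(np.ceil(len(variables) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.2 * ncol, 3.2 * nrow))
    for ax, var in zip(np.ravel(axes), variables):
        data, positions, colors = [], [], []
        for ci, k in enumerate(clusters):
            for off, (flag, color) in enumerate(
                ((True, "tab:blue"), (False, "tab:grey"))
            ):
                vals = scored.loc[
                    (scored["cluster"] == k) & (scored["is_presence"] == flag), var
                ].to_numpy()
                data.append(vals if len(vals) else [np.nan])
                positions.append(ci + (off - 0.5) * 0.35)
                colors.append(color)
        bp = ax.boxplot(data, positions=positions, widths=0.3,
                        patch_artist=True, showfliers=False)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
            patch.set_alpha(0.6)
        ax.set_xticks(range(len(clusters)))
        ax.set_xticklabels([str(k + 1) for k in clusters])
        ax.set_title(var, fontsize=9)
    for ax in np.ravel(axes)[len(variables):]:
        ax.axis("off")
    fig.suptitle("habitat clusters: presence (blue) vs absence (grey)", y=1.0)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
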