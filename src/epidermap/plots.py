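"""Diagnostic figures: PCA maps, k-selection curves, spatial densities."""

from __future__ import annotations

import numpy as np

from .datatypes import ClusterModel


def _get_ax(ax):
    if ax is not None:
        return ax.figure, ax
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=(5, 4))


def plot_pca(result, ax=None):
    """Scatter of the first two PCs coloured by archetype-matched cluster."""
    fig, ax = _get_ax(ax)
    gated = result.gated
    scores = result.pca_scores
    for cluster in sorted(gated["cluster"].dropna().unique()):
        sel = (gated["cluster"] == cluster).to_numpy()
        ax.scatter(scores[sel, 0], scores[sel, 1], s=4, alpha=0.5, label=f"cluster {cluster}")
    var = result.pca_variance
    ax.set_xlabel(f"PC1 ({var[0]:.0%})")
    ax.set_ylabel(f"PC2 ({var[1]:.0%})")
    ax.legend(markerscale=3, fontsize=8)
    return fig, ax


def plot_k_selection(model: ClusterModel, ax=None):
    """WSS (elbow) and mean-silhouette curves over candidate k."""
    fig, ax = _get_ax(ax)
    ks = sorted(model.wss_by_k)
    ax.plot(ks, [model.wss_by_k[k] for k in ks], "o-", color="tab:blue", label="WSS")
    ax.set_xlabel("k")
    ax.set_ylabel("within-cluster SS", color="tab:blue")
    ax2 = ax.twinx()
    sks = sorted(model.silhouette_by_k)
    ax2.plot(
        sks, [model.silhouette_by_k[k] for k in sks], "s--", color="tab:red",
        label="mean silhouette",
    )
    ax2.set_ylabel("mean silhouette", color="tab:red")
    ax.axvline(model.chosen_k, color="gray", ls=":", label=f"chosen k={model.chosen_k}")
    return fig, ax


def plot_hf_density(table, ax=None, grid_size=128):
    """BrdU-vs-follicle-distance density map with the cell scatter."""
    from .spatial import kde_density

    fig, ax = _get_ax(ax)
    ok = np.isfinite(table["dist_hf"])
    x = table.loc[ok, "dist_hf"].to_numpy()
    y = table.loc[ok, "brdu_mean"].to_numpy()
    xg, yg, d = kde_density(x, y, grid_size=grid_size)
    ax.pcolormesh(xg, yg, d, shading="auto", cmap="viridis")
    ax.scatter(x, y, s=1, c="white", alpha=0.15)
    ax.set_xlabel("distance to hair follicle (µm)")
    ax.set_ylabel("BrdU mean intensity (a.u.)")
    return fig, ax


def plot_composition(composition, ax=None):
    """Stacked cluster-composition bars per distance group or timepoint."""
    fig, ax = _get_ax(ax)
    idx_col = composition.columns[0]
    table = composition.set_index(idx_col)
    bottom = np.zeros(len(table))
    for col in table.columns:
        ax.bar(table.index.astype(str), table[col].to_numpy(), bottom=bottom, label=col)
        bottom += table[col].to_numpy()
    ax.set_ylabel("fraction of cells")
    ax.legend(fontsize=8)
    return fig, ax
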