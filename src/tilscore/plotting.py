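"""Diagnostic plots: clustered similarity heatmaps and quality scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # non-interactive backend; callers save figures

import matplotlib.pyplot as plt
import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = ["similarity_heatmap", "quality_scatter"]


def similarity_heatmap(sim_matrix, selected=(), title: str = "", ax=None):
    """Heatmap of a gene x gene similarity matrix, leaves ordered by clustering.

    Selected marker genes are highlighted in the tick labels (bold, green),
    mirroring the sidebar convention of published marker-QC heatmaps.
    """
    values = sim_matrix.values
    genes = list(values.index)
    if len(genes) > 2:
        dist = (1.0 - values.to_numpy()).clip(min=0.0)
        np.fill_diagonal(dist, 0.0)
        link = sch.linkage(squareform(dist, checks=False), method="average")
        order = sch.leaves_list(link)
        genes = [genes[i] for i in order]
    data = values.loc[genes, genes].to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * len(genes) + 2,) * 2)
    im = ax.imshow(data, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    sel = set(selected)
    for tick in list(ax.get_xticklabels()) + list(ax.get_yticklabels()):
        if tick.get_text() in sel:
            tick.set_color("darkgreen")
            tick.set_fontweight("bold")
    ax.figure.colorbar(im, ax=ax, label="pairwise similarity", shrink=0.7)
    if title:
        ax.set_title(title)
    return ax


def quality_scatter(reports, ax=None):
    """Mean log2 expression vs mean pairwise similarity per cell type.

    Cell types with weakly co-expressed markers concentrate at low mean
    expression, the signature of measurement noise dominating the signal.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for r in reports:
        if r.mean_pairwise_similarity is None or r.mean_log2_expression is None:
            continue
        ok = r.cell_type_status == "accepted"
        ax.scatter(
            r.mean_log2_expression,
            r.mean_pairwise_similarity,
            color="tab:blue" if ok else "grey",
        )
        ax.annotate(
            r.cell_type,
            (r.mean_log2_expression, r.mean_pairwise_similarity),
            fontsize=8,
            xytext=(4, 2),
            textcoords="offset points",
        )
    ax.set_xlabel("mean log2 expression of selected markers")
    ax.set_ylabel("mean pairwise similarity")
    return ax
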