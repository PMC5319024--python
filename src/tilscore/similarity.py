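"""Pairwise co-expression similarity statistic and marker-gene selection.

Two ideal marker genes for the same cell type are, in log expression,
perfectly correlated with slope 1: both simply track the log abundance of the
cell type, each offset by its own per-cell expression constant.  The
similarity statistic

    similarity(x, y) = sum((x - mean(x)) (y - mean(y)))
                       / [ (n - 1)/2 * (var(x) + var(y)) ]
                     = 2 cov(x, y) / (var(x) + var(y))

equals 1 exactly in that case and decreases both with falling correlation and
with slopes diverging from 1.  It relates to Pearson's r by

    similarity = r * 2 s_x s_y / (s_x^2 + s_y^2),

so |similarity| <= |r| with equality iff the two variances agree (AM-GM).
The multiplicative penalty depends only on the SD ratio, which is what lets
selection distinguish a merely low-correlation gene from a gene that is
highly correlated but rises at the wrong rate.

Selection clusters candidate genes by average-linkage hierarchical clustering
of 1 - similarity, takes the largest cluster whose mean off-diagonal
similarity clears a threshold (0.6 preferred, 0.4 fallback), and then prunes
slope outliers: genes whose Pearson correlation to the rest of the cluster
greatly exceeds their similarity are co-regulated but not expressed at a
stable per-cell level, and are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .expr_io import ExpressionMatrix, Scale
from .markers import CellTypeMarkers, DerivedScore, MarkerSet, canonical_symbol

__all__ = [
    "pairwise_similarity",
    "similarity_matrix",
    "average_similarity",
    "select_markers",
    "cell_type_quality",
    "SimilarityMatrix",
    "SelectionReport",
    "MarkerSelectionModel",
    "MarkerSelectionResults",
]

#: Discard reasons recorded per candidate gene.
LOW_SIMILARITY = "low_similarity"
NON_UNIT_SLOPE = "non_unit_slope_cluster"
DOMAIN_EXCLUSION = "domain_exclusion"
ABSENT = "absent_from_data"

ACCEPTED = "accepted"
DISCARDED_LOW_SIMILARITY = "discarded_low_similarity"
SINGLE_GENE_UNVALIDATED = "single_gene_unvalidated"


def pairwise_similarity(x, y) -> float:
    """Similarity statistic 2*cov(x, y) / (var(x) + var(y)) in [-1, 1].

    Uses unbiased (n-1) sample variances. Errors on vectors shorter than 3,
    mismatched lengths, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0.0 or vy == 0.0:
        raise ValueError("degenerate gene: zero variance")
    # the (n-1) factors in numerator covariance and denominator cancel
    return float(2.0 * (xc @ yc) / (vx + vy))


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene similarity values with provenance.

    ``correlation`` carries the matching Pearson matrix when the source data
    were available (selection uses it to recognize non-unit-slope genes);
    ``n_contributing`` carries per-pair dataset counts for averaged matrices.
    """

    values: pd.DataFrame
    n_samples: int = 0
    dataset_label: str = ""
    correlation: pd.DataFrame | None = None
    absent_genes: list[str] = field(default_factory=list)
    dropped_genes: list[str] = field(default_factory=list)
    n_contributing: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def submatrix(self, genes: Sequence[str]) -> pd.DataFrame:
        genes = [g for g in genes if g in self.values.index]
        return self.values.loc[genes, genes]

    def mean_offdiag(self, genes: Sequence[str] | None = None) -> float:
        """Mean of the off-diagonal similarity entries among ``genes``."""
        sub = self.submatrix(genes if genes is not None else self.gene_ids)
        k = sub.shape[0]
        if k < 2:
            raise ValueError("need at least 2 genes for a mean pairwise similarity")
        a = sub.to_numpy()
        return float((a.sum() - np.trace(a)) / (k * (k - 1)))


def _pairwise_matrices(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs similarity and Pearson matrices for a g x n value array."""
    n = vals.shape[1]
    centered = vals - vals.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n - 1)
    var = np.diag(cov)
    sim = 2.0 * cov / (var[:, None] + var[None, :])
    sd = np.sqrt(var)
    corr = cov / (sd[:, None] * sd[None, :])
    np.fill_diagonal(sim, 1.0)
    np.fill_diagonal(corr, 1.0)
    return sim, corr


def similarity_matrix(
    m: ExpressionMatrix | pd.DataFrame,
    genes: Sequence[str],
    dataset_label: str = "",
) -> SimilarityMatrix:
    """All-pairs similarity among ``genes`` in one log2 expression matrix.

    Genes absent from the matrix are recorded in ``absent_genes``; genes with
    zero variance are dropped with a warning.  At least two usable genes are
    required.
    """
    if isinstance(m, ExpressionMatrix):
        if m.scale is not Scale.log2:
            raise ValueError("similarity_matrix expects log2-scale expression")
        data = m.data
    else:
        data = m
    genes = [canonical_symbol(g) for g in genes]
    present = [g for g in dict.fromkeys(genes) if g in data.index]
    absent = [g for g in dict.fromkeys(genes) if g not in data.index]
    vals = data.loc[present].to_numpy(dtype=float)
    variances = vals.var(axis=1, ddof=1) if present else np.array([])
    dropped = [g for g, v in zip(present, variances) if v == 0.0]
    if dropped:
        warnings.warn(f"zero-variance genes dropped: {', '.join(dropped)}")
        keep = [g for g in present if g not in dropped]
        vals = data.loc[keep].to_numpy(dtype=float)
        present = keep
    if len(present) < 2:
        raise ValueError("fewer than 2 usable genes for a similarity matrix")
    sim, corr = _pairwise_matrices(vals)
    return SimilarityMatrix(
        values=pd.DataFrame(sim, index=present, columns=present),
        n_samples=data.shape[1],
        dataset_label=dataset_label,
        correlation=pd.DataFrame(corr, index=present, columns=present),
        absent_genes=absent,
        dropped_genes=dropped,
    )


def average_similarity(matrices: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Per-pair unweighted mean similarity across datasets.

    Each dataset contributes equally to every pair it covers; pairs absent
    from all datasets are NaN, and per-pair contributing-dataset counts are
    kept so callers can filter thinly supported pairs.
    """
    if not matrices:
        raise ValueError("need at least one similarity matrix")
    genes: list[str] = []
    for sm in matrices:
        for g in sm.gene_ids:
            if g not in genes:
                genes.append(g)
    sim_sum = pd.DataFrame(0.0, index=genes, columns=genes)
    corr_sum = pd.DataFrame(0.0, index=genes, columns=genes)
    count = pd.DataFrame(0, index=genes, columns=genes)
    have_corr = all(sm.correlation is not None for sm in matrices)
    for sm in matrices:
        g = sm.gene_ids
        sim_sum.loc[g, g] += sm.values
        count.loc[g, g] += 1
        if have_corr:
            corr_sum.loc[g, g] += sm.correlation
    with np.errstate(invalid="ignore"):
        avg = sim_sum / count.where(count > 0)
        avg_corr = corr_sum / count.where(count > 0) if have_corr else None
    absent = sorted(set().union(*(sm.absent_genes for sm in matrices)) - set(genes))
    return SimilarityMatrix(
        values=avg,
        n_samples=sum(sm.n_samples for sm in matrices),
        dataset_label=f"mean of {len(matrices)} datasets",
        correlation=avg_corr,
        absent_genes=absent,
        n_contributing=count,
    )


@dataclass
class SelectionReport:
    """Outcome of marker selection for one cell type."""

    cell_type: str
    candidates: list[str]
    selected: list[str]
    discarded: list[tuple[str, str]]  # (gene, reason)
    mean_pairwise_similarity: float | None
    cell_type_status: str
    mean_log2_expression: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per candidate gene with its fate and reason code."""
        reasons = dict(self.discarded)
        rows = [
            {
                "cell_type": self.cell_type,
                "gene": g,
                "selected": g in self.selected,
                "reason": "" if g in self.selected else reasons.get(g, ""),
            }
            for g in self.candidates
        ]
        return pd.DataFrame(rows)


def _tree_clusters(link: np.ndarray, labels: list[str]) -> list[list[str]]:
    """All internal-node clusters (size >= 2) of a linkage tree."""
    members: dict[int, list[int]] = {i: [i] for i in range(len(labels))}
    out: list[list[str]] = []
    for step, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] + members[int(b)]
        members[len(labels) + step] = merged
        out.append(sorted(labels[i] for i in merged))
    return out


def _prune_slope_outliers(
    cluster: list[str],
    sim: pd.DataFrame,
    corr: pd.DataFrame,
    slope_gap: float,
    moderate_threshold: float,
) -> tuple[list[str], list[str]]:
    """Iteratively remove genes correlated with the cluster at a non-unit slope.

    A gene whose mean Pearson r to the rest of the cluster exceeds its mean
    similarity by more than ``slope_gap`` (while r itself clears the moderate
    threshold) is co-regulated with the cluster but rises at a different
    rate.  The largest gap is removed first and gaps recomputed; a final pair
    is never split because the outlier would be unidentifiable.
    """
    kept = list(cluster)
    pruned: list[str] = []
    while len(kept) > 2:
        gaps = {}
        for g in kept:
            rest = [h for h in kept if h != g]
            mean_r = float(corr.loc[g, rest].mean())
            mean_s = float(sim.loc[g, rest].mean())
            if mean_r > moderate_threshold and (mean_r - mean_s) > slope_gap:
                gaps[g] = mean_r - mean_s
        if not gaps:
            break
        worst = max(sorted(gaps), key=gaps.get)
        kept.remove(worst)
        pruned.append(worst)
    return kept, pruned


def select_markers(
    avg: SimilarityMatrix,
    candidates: Sequence[str],
    high_threshold: float = 0.6,
    moderate_threshold: float = 0.4,
    exclusions: Sequence[str] = (),
    cell_type: str = "",
    linkage_method: str = "average",
    slope_gap: float = 0.1,
) -> SelectionReport:
    """Select the marker-like subset of ``candidates`` from a similarity matrix.

    Average-linkage hierarchical clustering on 1 - similarity is cut at every
    height; among the resulting clusters the largest whose mean off-diagonal
    similarity exceeds ``high_threshold`` is selected (falling back to
    ``moderate_threshold``, else an empty selection), ties broken by
    lexicographic gene order.  When the matrix carries Pearson correlations,
    genes correlated with the cluster at a clearly non-unit slope are then
    pruned (see :func:`_prune_slope_outliers`); finally ``exclusions`` are
    removed as domain-knowledge overrides.
    """
    candidates = [canonical_symbol(g) for g in dict.fromkeys(candidates)]
    exclusions = {canonical_symbol(g) for g in exclusions}
    if not candidates:
        raise ValueError("no candidate genes supplied")
    discarded: list[tuple[str, str]] = []
    present = []
    for g in candidates:
        if g in avg.values.index and not avg.values.loc[g].drop(g).isna().all():
            present.append(g)
        else:
            discarded.append((g, ABSENT))

    if len(present) == 1:
        g = present[0]
        selected = [] if g in exclusions else [g]
        if g in exclusions:
            discarded.append((g, DOMAIN_EXCLUSION))
        return SelectionReport(
            cell_type, candidates, selected, discarded, None, SINGLE_GENE_UNVALIDATED
        )
    if not present:
        return SelectionReport(
            cell_type, candidates, [], discarded, None, DISCARDED_LOW_SIMILARITY
        )

    sim = avg.values.loc[present, present].fillna(0.0)
    dist = (1.0 - sim.to_numpy()).clip(min=0.0)
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(squareform(dist, checks=False), method=linkage_method)
    clusters = _tree_clusters(link, present)

    def offdiag_mean(genes: list[str]) -> float:
        a = sim.loc[genes, genes].to_numpy()
        k = len(genes)
        return float((a.sum() - np.trace(a)) / (k * (k - 1)))

    chosen: list[str] = []
    for threshold in (high_threshold, moderate_threshold):
        qualifying = [c for c in clusters if offdiag_mean(c) > threshold]
        if qualifying:
            size = max(len(c) for c in qualifying)
            chosen = min(c for c in qualifying if len(c) == size)
            break

    if chosen and avg.correlation is not None:
        corr = avg.correlation.loc[present, present].fillna(0.0)
        chosen, pruned = _prune_slope_outliers(
            chosen, sim, corr, slope_gap, moderate_threshold
        )
        discarded.extend((g, NON_UNIT_SLOPE) for g in pruned)

    for g in present:
        if g in chosen:
            continue
        if any(g == d for d, _ in discarded):
            continue
        reason = LOW_SIMILARITY
        if avg.correlation is not None and chosen:
            mean_r = float(avg.correlation.loc[g, chosen].mean())
            mean_s = float(sim.loc[g, chosen].mean())
            if mean_r > moderate_threshold and (mean_r - mean_s) > slope_gap:
                reason = NON_UNIT_SLOPE
        discarded.append((g, reason))

    selected = [g for g in chosen if g not in exclusions]
    discarded.extend((g, DOMAIN_EXCLUSION) for g in chosen if g in exclusions)

    mean_sim = offdiag_mean(selected) if len(selected) >= 2 else None
    if mean_sim is not None and mean_sim > moderate_threshold:
        status = ACCEPTED
    else:
        status = DISCARDED_LOW_SIMILARITY
    return SelectionReport(cell_type, candidates, selected, discarded, mean_sim, status)


def cell_type_quality(
    reports: Sequence[SelectionReport],
    discard_threshold: float = 0.4,
    expression: ExpressionMatrix | pd.DataFrame | None = None,
) -> list[SelectionReport]:
    """Final accept/discard call per cell type by mean pairwise similarity.

    Cell types whose selected markers average below ``discard_threshold`` are
    discarded; single-gene cell types are retained unvalidated.  When an
    expression matrix is given, the mean log2 expression of each cell type's
    selected genes is attached as a low-expression diagnostic (weak marker
    behaviour concentrates at low expression, where measurement error bites).
    """
    data = expression.data if isinstance(expression, ExpressionMatrix) else expression
    out = []
    for r in reports:
        status = r.cell_type_status
        if status == ACCEPTED and (
            r.mean_pairwise_similarity is None
            or r.mean_pairwise_similarity < discard_threshold
        ):
            status = DISCARDED_LOW_SIMILARITY
        mean_expr = r.mean_log2_expression
        if data is not None and r.selected:
            genes = [g for g in r.selected if g in data.index]
            if genes:
                mean_expr = float(data.loc[genes].to_numpy().mean())
        out.append(
            SelectionReport(
                r.cell_type, r.candidates, r.selected, r.discarded,
                r.mean_pairwise_similarity, status, mean_expr,
            )
        )
    return out


class MarkerSelectionModel:
    """Marker-gene QC across one or more log2 expression datasets.

    Parameters
    ----------
    datasets : sequence of ExpressionMatrix or DataFrame
        Bulk tumor expression, log2 scale, genes x samples.
    candidates : mapping of cell type -> candidate gene list
        Literature-derived candidate markers to validate.
    exclusions : mapping of cell type -> gene list, optional
        Domain-knowledge overrides removed from any selection.
    dataset_labels : sequence of str, optional

    Examples
    --------
    >>> model = MarkerSelectionModel([log2_expr], {"B-cells": genes})
    >>> res = model.fit()
    >>> res.summary()          # doctest: +SKIP
    """

    def __init__(
        self,
        datasets: Sequence[ExpressionMatrix | pd.DataFrame],
        candidates: Mapping[str, Sequence[str]],
        exclusions: Mapping[str, Sequence[str]] | None = None,
        dataset_labels: Sequence[str] | None = None,
    ):
        if not datasets:
            raise ValueError("need at least one dataset")
        if not candidates:
            raise ValueError("need at least one cell type with candidates")
        self.datasets = list(datasets)
        self.candidates = {k: list(v) for k, v in candidates.items()}
        self.exclusions = {k: list(v) for k, v in (exclusions or {}).items()}
        self.dataset_labels = list(
            dataset_labels or (f"dataset_{i}" for i in range(len(datasets)))
        )

    def fit(
        self,
        high_threshold: float = 0.6,
        moderate_threshold: float = 0.4,
        discard_threshold: float = 0.4,
        linkage_method: str = "average",
        slope_gap: float = 0.1,
    ) -> "MarkerSelectionResults":
        per_dataset: dict[str, list[SimilarityMatrix]] = {}
        averaged: dict[str, SimilarityMatrix] = {}
        reports: list[SelectionReport] = []
        for cell_type, genes in self.candidates.items():
            uniq = [canonical_symbol(g) for g in dict.fromkeys(genes)]
            if len(uniq) == 1:
                # a lone candidate has no co-expression partner; retained
                # unvalidated when present in the data at all
                g = uniq[0]
                in_data = any(
                    g in (ds.data.index if isinstance(ds, ExpressionMatrix) else ds.index)
                    for ds in self.datasets
                )
                excl = {canonical_symbol(e) for e in self.exclusions.get(cell_type, ())}
                if not in_data:
                    report = SelectionReport(
                        cell_type, uniq, [], [(g, ABSENT)], None,
                        DISCARDED_LOW_SIMILARITY,
                    )
                elif g in excl:
                    report = SelectionReport(
                        cell_type, uniq, [], [(g, DOMAIN_EXCLUSION)], None,
                        SINGLE_GENE_UNVALIDATED,
                    )
                else:
                    report = SelectionReport(
                        cell_type, uniq, [g], [], None, SINGLE_GENE_UNVALIDATED
                    )
                per_dataset[cell_type] = []
                averaged[cell_type] = SimilarityMatrix(values=pd.DataFrame())
                reports.append(report)
                continue
            mats = []
            for ds, label in zip(self.datasets, self.dataset_labels):
                try:
                    mats.append(similarity_matrix(ds, genes, dataset_label=label))
                except ValueError:
                    continue  # < 2 usable genes in this dataset
            if mats:
                avg = average_similarity(mats)
            else:
                avg = SimilarityMatrix(values=pd.DataFrame(), absent_genes=list(genes))
            per_dataset[cell_type] = mats
            averaged[cell_type] = avg
            reports.append(
                select_markers(
                    avg, genes, high_threshold, moderate_threshold,
                    self.exclusions.get(cell_type, ()), cell_type,
                    linkage_method, slope_gap,
                )
            )
        first = self.datasets[0]
        reports = cell_type_quality(reports, discard_threshold, expression=first)
        return MarkerSelectionResults(self, reports, averaged, per_dataset)


class MarkerSelectionResults:
    """Fitted marker selection: per-cell-type reports and similarity matrices."""

    def __init__(self, model, reports, averaged, per_dataset):
        self.model = model
        self.reports: dict[str, SelectionReport] = {r.cell_type: r for r in reports}
        self.similarity: dict[str, SimilarityMatrix] = averaged
        self.per_dataset: dict[str, list[SimilarityMatrix]] = per_dataset

    def summary(self) -> pd.DataFrame:
        """Quality table: candidates, selected markers, mean similarity, status."""
        rows = []
        for name, r in self.reports.items():
            rows.append(
                {
                    "cell_type": name,
                    "n_candidates": len(r.candidates),
                    "n_selected": len(r.selected),
                    "mean_pairwise_similarity": r.mean_pairwise_similarity,
                    "mean_log2_expression": r.mean_log2_expression,
                    "status": r.cell_type_status,
                    "selected_markers": ", ".join(r.selected),
                }
            )
        return pd.DataFrame(rows).set_index("cell_type")

    def to_marker_set(self, include_unvalidated: bool = True) -> MarkerSet:
        """Convert accepted (and optionally single-gene) cell types to a MarkerSet."""
        keep = {ACCEPTED}
        if include_unvalidated:
            keep.add(SINGLE_GENE_UNVALIDATED)
        cell_types = [
            CellTypeMarkers(
                r.cell_type, r.selected,
                single_gene=r.cell_type_status == SINGLE_GENE_UNVALIDATED,
                n_candidates=len(r.candidates),
                mean_similarity=r.mean_pairwise_similarity,
            )
            for r in self.reports.values()
            if r.cell_type_status in keep and r.selected
        ]
        return MarkerSet(cell_types)

    def selection_frame(self) -> pd.DataFrame:
        """Per-gene selection outcomes for all cell types (TSV-friendly)."""
        return pd.concat(
            [r.to_frame() for r in self.reports.values()], ignore_index=True
        )

    def plot_similarity(self, cell_type: str, ax=None):
        from .plotting import similarity_heatmap

        return similarity_heatmap(
            self.similarity[cell_type],
            selected=self.reports[cell_type].selected,
            title=cell_type,
            ax=ax,
        )

    def plot_quality(self, ax=None):
        from .plotting import quality_scatter

        return quality_scatter(list(self.reports.values()), ax=ax)
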