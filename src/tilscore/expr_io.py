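"""Expression matrix I/O, normalization, and log transformation.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a genes x samples :class:`pandas.DataFrame` that tracks which scale the
values live on (raw counts, linearly normalized, or log2).  All downstream
statistics in this package operate on log2 values, where one unit corresponds
to one doubling of expression.

Reference-gene normalization follows the standard nCounter-style workflow:
stable reference genes are chosen by their pairwise log-ratio stability
(the geNorm M statistic), each sample is divided by the geometric mean of its
reference genes, and the result is rescaled back to an intelligible count
space by the grand geometric mean of those per-sample factors.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import canonical_symbol

__all__ = [
    "Scale",
    "ExpressionMatrix",
    "ReferenceGenePanel",
    "read_expression",
    "log2_transform",
    "genorm_select_references",
    "reference_normalize",
]


class Scale(str, enum.Enum):
    """Scale of the values held by an :class:`ExpressionMatrix`."""

    raw_counts = "raw_counts"
    linear_normalized = "linear_normalized"
    log2 = "log2"


class ExpressionError(ValueError):
    """Invalid expression matrix contents or incompatible operation."""


def _find_duplicates(labels) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in labels:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a known scale.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample identifier.
    scale : Scale
        Scale of the values. Raw counts and linear-normalized values must be
        non-negative.
    meta : dict
        Free-form provenance (e.g. the pseudocount used by log transformation).
    """

    data: pd.DataFrame
    scale: Scale = Scale.raw_counts
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = pd.Index([canonical_symbol(g) for g in self.data.index])
        self.data.columns = pd.Index([str(c) for c in self.data.columns])
        dup_g = _find_duplicates(self.data.index)
        if dup_g:
            raise ExpressionError(f"duplicate gene identifiers: {', '.join(dup_g)}")
        dup_s = _find_duplicates(self.data.columns)
        if dup_s:
            raise ExpressionError(f"duplicate sample identifiers: {', '.join(dup_s)}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(values))
            raise ExpressionError(f"non-numeric values at (row, col) {bad[:5].tolist()}")
        if self.scale is not Scale.log2 and np.nanmin(values, initial=np.inf) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ExpressionError(
                f"negative value on {self.scale.value} scale at gene "
                f"{self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene(self, symbol: str) -> pd.Series:
        """Expression of one gene across samples (alias-aware lookup)."""
        return self.data.loc[canonical_symbol(symbol)]

    def __contains__(self, symbol: str) -> bool:
        return canonical_symbol(symbol) in self.data.index

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale, dict(self.meta))


@dataclass
class ReferenceGenePanel:
    """A set of reference genes chosen for their expression stability.

    ``stability`` maps each candidate to its final-round geNorm M value
    (mean standard deviation of its pairwise log2 ratios; lower = more
    stable). ``exclusion_order`` lists removed genes from least to most
    stable so callers may cut the trajectory anywhere.
    """

    candidate_genes: list[str]
    selected_genes: list[str]
    stability: dict[str, float]
    exclusion_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.selected_genes) <= set(self.candidate_genes):
            raise ValueError("selected_genes must be a subset of candidate_genes")
        if len(self.selected_genes) < 2:
            raise ValueError("a reference panel needs at least 2 genes")


def read_expression(
    path: str | Path,
    *,
    delimiter: str | None = None,
    orientation: str = "genes_by_samples",
    scale: Scale | str = Scale.raw_counts,
) -> ExpressionMatrix:
    """Read a delimited expression matrix from ``path``.

    Parameters
    ----------
    delimiter : str, optional
        Field delimiter; sniffed from the extension when omitted
        (``.csv`` -> comma, else tab).
    orientation : {"genes_by_samples", "samples_by_genes"}
        Whether rows are genes (default) or samples; the latter is transposed
        on read so the returned matrix is always genes x samples.
    scale : Scale
        Declared scale of the stored values.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & df.notna()
        coords = [
            f"(row {df.index[i]!r}, column {df.columns[j]!r})"
            for i, j in zip(*np.where(bad.to_numpy()))
        ]
        raise ExpressionError(
            f"non-numeric cell(s) in {path.name} at {', '.join(coords[:5])}"
        ) from exc
    return ExpressionMatrix(df, Scale(scale), meta={"source": str(path)})


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(value + pseudocount)`` of a linear-scale matrix.

    The default pseudocount of 1 maps zero counts to zero and leaves high
    expression essentially untouched; it is recorded in the output metadata.
    """
    if m.scale is Scale.log2:
        raise ExpressionError("already log scale")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    out = np.log2(m.data + pseudocount)
    meta = dict(m.meta, pseudocount=pseudocount)
    return ExpressionMatrix(out, Scale.log2, meta)


def _genorm_m(log2_vals: np.ndarray) -> np.ndarray:
    """geNorm stability M for each of g genes given a g x n log2 matrix.

    M_j = mean over partners k != j of SD across samples of log2(x_j/x_k).
    """
    g = log2_vals.shape[0]
    m = np.empty(g)
    for j in range(g):
        ratios = log2_vals[j] - log2_vals  # g x n, row j is zeros
        sds = np.std(ratios, axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return m


def genorm_select_references(
    m: ExpressionMatrix,
    candidates: list[str],
    min_genes: int = 3,
) -> ReferenceGenePanel:
    """Choose stable reference genes by iterative geNorm elimination.

    The least stable gene (highest M) is removed and M recomputed until
    ``min_genes`` remain.  Genes containing zeros are excluded up front with a
    warning because their log-ratios are undefined.
    """
    if m.scale is Scale.log2:
        raise ExpressionError("genorm_select_references expects linear-scale counts")
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    candidates = [canonical_symbol(c) for c in candidates]
    usable = []
    for c in candidates:
        if c not in m.data.index:
            warnings.warn(f"reference candidate {c} absent from matrix; skipped")
            continue
        if (m.data.loc[c] <= 0).any():
            warnings.warn(f"reference candidate {c} has zero/negative counts; skipped")
            continue
        usable.append(c)
    if len(usable) < min_genes:
        raise ExpressionError(
            f"only {len(usable)} usable reference candidates, need >= {min_genes}"
        )
    vals = np.log2(m.data.loc[usable].to_numpy(dtype=float))
    remaining = list(usable)
    exclusion_order: list[str] = []
    stability: dict[str, float] = {}
    while True:
        mm = _genorm_m(vals)
        stability.update(dict(zip(remaining, mm)))
        if len(remaining) <= min_genes:
            break
        worst = int(np.argmax(mm))
        exclusion_order.append(remaining[worst])
        del remaining[worst]
        vals = np.delete(vals, worst, axis=0)
    return ReferenceGenePanel(
        candidate_genes=usable,
        selected_genes=list(remaining),
        stability=stability,
        exclusion_order=exclusion_order,
    )


def reference_normalize(
    m: ExpressionMatrix, panel: ReferenceGenePanel
) -> ExpressionMatrix:
    """Normalize each sample to the geometric mean of its reference genes.

    Every sample's profile is divided by the geometric mean of the panel's
    selected genes in that sample, then multiplied by the grand geometric mean
    of those per-sample factors so the output remains in count space.  After
    normalization the reference-gene geometric mean is identical in every
    sample, which also makes the operation idempotent.
    """
    if m.scale is Scale.log2:
        raise ExpressionError("reference_normalize expects linear-scale values")
    refs = [canonical_symbol(g) for g in panel.selected_genes]
    missing = [g for g in refs if g not in m.data.index]
    if missing:
        raise ExpressionError(f"reference genes absent from matrix: {', '.join(missing)}")
    ref_vals = m.data.loc[refs]
    bad = ref_vals <= 0
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionError(
            f"non-positive reference count for gene {refs[g]!r} in sample "
            f"{m.sample_ids[s]!r}"
        )
    log_f = np.log(ref_vals).mean(axis=0)  # per-sample log geometric mean
    factors = np.exp(log_f)
    grand = float(np.exp(log_f.mean()))
    out = m.data.div(factors, axis=1) * grand
    meta = dict(m.meta, reference_genes=list(refs), grand_reference_geomean=grand)
    return ExpressionMatrix(out, Scale.linear_normalized, meta)
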