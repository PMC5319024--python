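"""Cell-type abundance scores, Total TILs, enrichment, and calibration.

A cell score is the arithmetic mean of the cell type's marker genes' log2
expression.  Under the model that each marker is expressed at a fixed (but
unknown) number of copies per cell, the score equals the log2 abundance of
the cell type plus an unknown constant: scores compare abundance across
samples (one unit = one doubling) but not across cell types without
calibration against a sample of known composition.

Total TILs summarizes overall infiltrate as the mean of the cell scores
sufficiently correlated with CD45 (PTPRC) expression; enrichment scores are
the residuals of each cell score regressed on Total TILs, measuring a cell
type's abundance relative to what its infiltrate level predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, Scale
from .markers import MarkerSet, canonical_symbol

__all__ = [
    "CellScoreTable",
    "cell_scores",
    "total_tils",
    "enrichment_scores",
    "calibrate_absolute",
    "fold_change",
    "relative_to_baseline",
    "normalize_to_cell_type",
    "CellScoreModel",
    "CellScoreResults",
]

CD45_GENE = "PTPRC"


@dataclass
class CellScoreTable:
    """Samples x cell types log2 scores with optional composite columns."""

    scores: pd.DataFrame  # samples x cell types
    total_tils: pd.Series | None = None
    enrichment: pd.DataFrame | None = None
    provenance: dict[str, list[str]] = field(default_factory=dict)
    tils_included: list[str] = field(default_factory=list)
    tils_excluded: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.columns)

    def copy(self) -> "CellScoreTable":
        return CellScoreTable(
            self.scores.copy(),
            None if self.total_tils is None else self.total_tils.copy(),
            None if self.enrichment is None else self.enrichment.copy(),
            {k: list(v) for k, v in self.provenance.items()},
            list(self.tils_included),
            list(self.tils_excluded),
            dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Scores with Total TILs and enrichment columns appended."""
        out = self.scores.copy()
        if self.total_tils is not None:
            out["Total TILs"] = self.total_tils
        if self.enrichment is not None:
            for c in self.enrichment.columns:
                out[f"{c} enrichment"] = self.enrichment[c]
        return out


def cell_scores(
    m: ExpressionMatrix | pd.DataFrame,
    markers: MarkerSet,
    allow_missing: bool = True,
) -> CellScoreTable:
    """Mean log2 marker expression per sample for each cell type.

    Marker genes absent from the matrix are skipped when ``allow_missing``
    (each score is then the mean of its available markers, the convention
    used on reduced gene panels); otherwise any absence is an error.  Derived
    scores (e.g. CD4 = T-cells - CD8 T cells) are computed afterwards and
    reported only when both parent scores exist.
    """
    if isinstance(m, ExpressionMatrix):
        if m.scale is not Scale.log2:
            raise ValueError("cell_scores expects log2-scale expression")
        data = m.data
    else:
        data = m
    cols: dict[str, pd.Series] = {}
    provenance: dict[str, list[str]] = {}
    for ct in markers:
        present = [g for g in dict.fromkeys(ct.genes) if g in data.index]
        missing = [g for g in ct.genes if g not in data.index]
        if missing and not allow_missing:
            raise ValueError(
                f"markers absent from matrix for {ct.name!r}: {', '.join(missing)}"
            )
        if not present:
            warnings.warn(f"cell type {ct.name!r} has no markers in the matrix; skipped")
            continue
        if missing:
            warnings.warn(
                f"cell type {ct.name!r}: scoring from {len(present)}/{len(ct.genes)}"
                f" available markers ({', '.join(missing)} missing)"
            )
        cols[ct.name] = data.loc[present].mean(axis=0)
        provenance[ct.name] = present
    if not cols:
        raise ValueError("no cell type could be scored from this matrix")
    scores = pd.DataFrame(cols)
    scores.index.name = "sample"
    for d in markers.derived_scores:
        if d.minuend in scores.columns and d.subtrahend in scores.columns:
            scores[d.name] = scores[d.minuend] - scores[d.subtrahend]
            provenance[d.name] = [f"{d.minuend} - {d.subtrahend}"]
        else:
            warnings.warn(
                f"derived score {d.name!r} skipped: needs both "
                f"{d.minuend!r} and {d.subtrahend!r}"
            )
    return CellScoreTable(scores, provenance=provenance)


def total_tils(
    scores: CellScoreTable,
    cd45: pd.Series | np.ndarray,
    threshold: float = 0.6,
    method: str = "pearson",
) -> CellScoreTable:
    """Total TILs: mean of the cell scores correlated with CD45 expression.

    Each cell score's correlation with per-sample CD45 (PTPRC) log2
    expression is computed across samples; scores exceeding ``threshold``
    are averaged into the composite, and the inclusion/exclusion split is
    recorded on the returned table.
    """
    out = scores.copy()
    if len(out.sample_ids) < 2:
        raise ValueError("need at least 2 samples to correlate with CD45")
    cd45 = pd.Series(np.asarray(cd45, dtype=float), index=out.scores.index)
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = out.scores.corrwith(cd45, method=method)
    included = [c for c in out.cell_types if corr[c] > threshold]
    excluded = [c for c in out.cell_types if c not in included]
    if not included:
        raise ValueError(
            "no cell score correlates with CD45 above the threshold; "
            "review the threshold or the CD45 vector"
        )
    out.total_tils = out.scores[included].mean(axis=1)
    out.total_tils.name = "Total TILs"
    out.tils_included = included
    out.tils_excluded = excluded
    out.meta["cd45_correlations"] = corr.to_dict()
    out.meta["tils_threshold"] = threshold
    return out


def enrichment_scores(scores: CellScoreTable) -> CellScoreTable:
    """Residuals of each cell score regressed on Total TILs (with intercept).

    An enrichment of 1 means the sample has twice the cell abundance expected
    of the average sample at the same Total TILs level.
    """
    out = scores.copy()
    if out.total_tils is None:
        raise ValueError("compute total_tils before enrichment scores")
    t = out.total_tils.to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to fit enrichment regressions")
    if np.var(t) == 0.0:
        raise ValueError("Total TILs has zero variance; enrichment undefined")
    tc = t - t.mean()
    resid = {}
    for c in out.cell_types:
        y = out.scores[c].to_numpy(dtype=float)
        beta = (tc @ (y - y.mean())) / (tc @ tc)
        resid[c] = y - (y.mean() + beta * tc)
    out.enrichment = pd.DataFrame(resid, index=out.scores.index)
    return out


def calibrate_absolute(
    score: float, reference_score: float, reference_count: float
) -> float:
    """Absolute cell count implied by a score and a calibrated reference.

    A reference sample with ``reference_count`` cells and score
    ``reference_score`` fixes the unknown constant; the query count is
    ``reference_count * 2**(score - reference_score)``.
    """
    if reference_count <= 0:
        raise ValueError("reference_count must be positive")
    return float(reference_count) * 2.0 ** (float(score) - float(reference_score))


def fold_change(score_difference: float) -> float:
    """Fold change in abundance implied by a log2 score difference."""
    return 2.0 ** float(score_difference)


def relative_to_baseline(
    scores: CellScoreTable, baseline_sample_ids: Sequence[str]
) -> CellScoreTable:
    """Report each score relative to its mean in a set of baseline samples.

    Used to place scores on an intuitive scale, e.g. log2 fold change from
    the average treatment-naive patient; baseline samples average to 0 in
    every column of the output.
    """
    baseline = list(baseline_sample_ids)
    if not baseline:
        raise ValueError("baseline sample list is empty")
    missing = [s for s in baseline if s not in scores.scores.index]
    if missing:
        raise ValueError(f"baseline samples absent from table: {', '.join(missing)}")
    out = scores.copy()
    means = out.scores.loc[baseline].mean(axis=0)
    out.scores = out.scores - means
    if out.total_tils is not None:
        out.total_tils = out.total_tils - out.total_tils.loc[baseline].mean()
    out.meta["baseline_samples"] = baseline
    return out


def normalize_to_cell_type(scores: CellScoreTable, anchor: str) -> CellScoreTable:
    """Express every score relative to one anchor cell type's score.

    Subtracting the anchor score per sample removes the per-sample
    normalization constant entirely, so the output contrasts (log2 ratios to
    the anchor) are valid even when reference-gene normalization is
    untrustworthy, as in samples whose cellular composition shifts.
    """
    out = scores.copy()
    if anchor not in out.scores.columns:
        raise ValueError(f"anchor cell type {anchor!r} not scored")
    out.scores = out.scores.sub(out.scores[anchor], axis=0)
    out.total_tils = None  # a composite of anchored scores is not meaningful
    out.meta["anchor"] = anchor
    return out


class CellScoreModel:
    """Scores a log2 expression matrix with a marker set, statsmodels-style.

    ``fit`` computes cell scores and optionally Total TILs (correlation with
    CD45 above a threshold) and enrichment residuals, returning a
    :class:`CellScoreResults`.

    Parameters
    ----------
    expression : ExpressionMatrix or DataFrame (genes x samples, log2)
    markers : MarkerSet, default the bundled TIL-60 set
    """

    def __init__(
        self,
        expression: ExpressionMatrix | pd.DataFrame,
        markers: MarkerSet | None = None,
        allow_missing: bool = True,
    ):
        if markers is None:
            from .markers import bundled_markers

            markers = bundled_markers()
        self.expression = expression
        self.markers = markers
        self.allow_missing = allow_missing

    def fit(
        self,
        compute_total_tils: bool = True,
        compute_enrichment: bool = True,
        tils_threshold: float = 0.6,
        tils_method: str = "pearson",
        frozen_tils_cell_types: Sequence[str] | None = None,
    ) -> "CellScoreResults":
        """Compute scores and composites.

        ``frozen_tils_cell_types`` bypasses the correlation rule and averages
        exactly the named scores, for reproducing a previously derived
        inclusion list on new data.
        """
        table = cell_scores(self.expression, self.markers, self.allow_missing)
        data = (
            self.expression.data
            if isinstance(self.expression, ExpressionMatrix)
            else self.expression
        )
        if compute_total_tils:
            if frozen_tils_cell_types is not None:
                cols = [c for c in frozen_tils_cell_types if c in table.scores.columns]
                if not cols:
                    raise ValueError("no frozen Total TILs cell type is scored")
                table.total_tils = table.scores[cols].mean(axis=1)
                table.total_tils.name = "Total TILs"
                table.tils_included = cols
                table.tils_excluded = [c for c in table.cell_types if c not in cols]
            else:
                cd45 = _cd45_vector(data, table)
                if cd45 is None:
                    warnings.warn(
                        "CD45 (PTPRC) unavailable; Total TILs not computed"
                    )
                else:
                    table = total_tils(table, cd45, tils_threshold, tils_method)
            if compute_enrichment and table.total_tils is not None:
                table = enrichment_scores(table)
        return CellScoreResults(self, table)


def _cd45_vector(data: pd.DataFrame, table: CellScoreTable) -> pd.Series | None:
    if CD45_GENE in data.index:
        return data.loc[CD45_GENE]
    for name in ("CD45", CD45_GENE):
        if name in table.scores.columns:
            return table.scores[name]
    return None


class CellScoreResults:
    """Fitted cell scores with composites, diagnostics and export helpers."""

    def __init__(self, model: CellScoreModel, table: CellScoreTable):
        self.model = model
        self.table = table

    @property
    def scores(self) -> pd.DataFrame:
        return self.table.scores

    @property
    def total_tils(self) -> pd.Series | None:
        return self.table.total_tils

    @property
    def enrichment(self) -> pd.DataFrame | None:
        return self.table.enrichment

    def summary(self) -> pd.DataFrame:
        """Per-cell-type summary: markers used, score spread, TILs inclusion."""
        rows = []
        for c in self.table.cell_types:
            rows.append(
                {
                    "cell_type": c,
                    "markers_used": ", ".join(self.table.provenance.get(c, [])),
                    "n_markers": len(self.table.provenance.get(c, [])),
                    "score_mean": float(self.table.scores[c].mean()),
                    "score_sd": float(self.table.scores[c].std(ddof=1)),
                    "in_total_tils": c in self.table.tils_included,
                }
            )
        return pd.DataFrame(rows).set_index("cell_type")

    def relative_to_baseline(self, baseline_sample_ids) -> CellScoreTable:
        return relative_to_baseline(self.table, baseline_sample_ids)

    def normalize_to_cell_type(self, anchor: str) -> CellScoreTable:
        return normalize_to_cell_type(self.table, anchor)
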