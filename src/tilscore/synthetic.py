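"""Synthetic bulk expression with known latent cell-type abundances.

The generator mirrors the measurement model behind marker-based scoring:
each cell type has a latent log2 abundance per sample, and a pure marker
gene contributes (copies per cell) x (cells), so its log2 expression is the
cell's log2 abundance plus a gene constant plus noise.  Beyond pure markers
it produces the gene archetypes relevant to co-expression QC:

* ``multi-cell contaminant`` — expressed by two or more cell types; its
  linear-scale contributions are summed before logging (physical mixing);
* ``non-unit slope`` — log2 expression rises at gamma units per abundance
  doubling (gamma != 1), the "highly correlated but wrong rate" archetype;
* ``noise gene`` — independent of all abundances.

Cell-type abundances share a latent "total infiltrate" factor (default
loading 0.7), reflecting the strong mutual correlation of immune cell
abundances observed in tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, Scale

__all__ = [
    "CellTypeSpec",
    "GeneSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate",
    "four_gene_scenario",
]

PURE_MARKER = "pure_marker"
CONTAMINANT = "multi_cell_contaminant"
NONLINEAR_SLOPE = "nonlinear_slope"
NOISE_GENE = "noise_gene"


@dataclass
class CellTypeSpec:
    """Latent abundance distribution of one simulated cell type (log2 scale)."""

    name: str
    log2_mean: float = 5.0
    log2_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.log2_sd < 0:
            raise ValueError(f"cell type {self.name!r}: negative abundance SD")


@dataclass
class GeneSpec:
    """One simulated gene.

    ``cell_weights`` maps cell type -> copies per cell on the linear scale;
    an empty mapping makes a noise gene (independent of all abundances).
    ``slope`` (gamma) only applies to single-cell-type genes and scales the
    log2 abundance; gamma != 1 produces the non-unit-slope archetype.
    ``baseline_log2`` sets a noise gene's mean log2 expression.
    """

    symbol: str
    cell_weights: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.1
    slope: float = 1.0
    baseline_log2: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"gene {self.symbol!r}: negative noise SD")
        if any(w <= 0 for w in self.cell_weights.values()):
            raise ValueError(f"gene {self.symbol!r}: copies per cell must be positive")
        if self.slope != 1.0 and len(self.cell_weights) != 1:
            raise ValueError(
                f"gene {self.symbol!r}: a non-unit slope applies only to a "
                "single-cell-type gene"
            )

    @property
    def role(self) -> str:
        if not self.cell_weights:
            return NOISE_GENE
        if len(self.cell_weights) > 1:
            return CONTAMINANT
        if self.slope != 1.0:
            return f"{NONLINEAR_SLOPE}({self.slope:g})"
        return f"{PURE_MARKER}({next(iter(self.cell_weights))})"


@dataclass
class SimulationConfig:
    """Full description of a synthetic bulk expression dataset."""

    n_samples: int
    cell_types: list[CellTypeSpec]
    genes: list[GeneSpec]
    infiltrate_loading: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        errors = []
        if self.n_samples < 1:
            errors.append("n_samples must be >= 1")
        if not 0.0 <= self.infiltrate_loading <= 1.0:
            errors.append("infiltrate_loading must be in [0, 1]")
        if self.seed is None:
            errors.append("seed is mandatory for reproducibility")
        names = {c.name for c in self.cell_types}
        if len(names) != len(self.cell_types):
            errors.append("duplicate cell type names")
        for g in self.genes:
            unknown = set(g.cell_weights) - names
            if unknown:
                errors.append(
                    f"gene {g.symbol!r} references unknown cell types: {sorted(unknown)}"
                )
        used = {c for g in self.genes for c in g.cell_weights}
        for c in self.cell_types:
            if c.name not in used:
                errors.append(f"cell type {c.name!r} has no gene expressing it")
        if errors:
            raise ValueError("invalid simulation config: " + "; ".join(errors))


@dataclass
class SimulatedDataset:
    """Synthetic expression plus ground truth."""

    expression: ExpressionMatrix  # log2 scale
    true_abundances: pd.DataFrame  # samples x cell types, log2
    gene_truth: dict[str, str]  # gene -> role
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from ``config``; deterministic given its seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lam = config.infiltrate_loading
    infiltrate = rng.standard_normal(n)
    abundances = {}
    for ct in config.cell_types:
        own = rng.standard_normal(n)
        z = lam * infiltrate + np.sqrt(1.0 - lam**2) * own
        abundances[ct.name] = ct.log2_mean + ct.log2_sd * z
    ab = pd.DataFrame(abundances)
    ab.index = [f"S{i:04d}" for i in range(n)]
    ab.index.name = "sample"

    rows = {}
    for g in config.genes:
        noise = rng.normal(0.0, g.noise_sd, n) if g.noise_sd > 0 else 0.0
        if not g.cell_weights:
            expr = g.baseline_log2 + noise
        elif len(g.cell_weights) == 1:
            (cell, w), = g.cell_weights.items()
            expr = np.log2(w) + g.slope * ab[cell].to_numpy() + noise
        else:
            linear = sum(
                w * np.exp2(ab[cell].to_numpy()) for cell, w in g.cell_weights.items()
            )
            expr = np.log2(linear) + noise
        rows[g.symbol] = expr
    expr_df = pd.DataFrame(rows, index=ab.index).T
    matrix = ExpressionMatrix(
        expr_df, Scale.log2, meta={"seed": config.seed, "synthetic": True}
    )
    truth = {g.symbol: g.role for g in config.genes}
    return SimulatedDataset(matrix, ab, truth, config)


def four_gene_scenario(
    n_samples: int = 500, seed: int = 20170221, noise_sd: float = 0.1
) -> SimulatedDataset:
    """Canned four-gene QC walkthrough with one latent cell type.

    GENE1 and GENE2 are ideal markers (unit slope, different per-cell
    constants); GENE3 is independent noise; GENE4 tracks the same cell type
    but with slope 2, so it is highly correlated with GENE1/GENE2 yet has a
    depressed similarity statistic (about 2*2/(1+4) = 0.8 at low noise).
    The default seed is fixed so the walkthrough is reproducible.
    """
    config = SimulationConfig(
        n_samples=n_samples,
        cell_types=[CellTypeSpec("CellA", log2_mean=5.0, log2_sd=1.0)],
        genes=[
            GeneSpec("GENE1", {"CellA": 2.0}, noise_sd=noise_sd),
            GeneSpec("GENE2", {"CellA": 8.0}, noise_sd=noise_sd),
            GeneSpec("GENE3", cell_weights={}, noise_sd=1.0, baseline_log2=6.0),
            GeneSpec("GENE4", {"CellA": 1.0}, noise_sd=noise_sd, slope=2.0),
        ],
        infiltrate_loading=0.0,
        seed=seed,
    )
    return simulate(config)
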