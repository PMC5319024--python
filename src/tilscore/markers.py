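"""Cell-type marker sets and gene-symbol canonicalization.

The bundled default set ("TIL-60") contains 60 marker genes covering 14
immune cell populations, plus a derived CD4 score defined as the T-cell
score minus the CD8 T-cell score. Matching is case-insensitive and a small
alias table absorbs common variant symbols (notably PTRPC, a widespread
misprint of PTPRC/CD45, and FAM30A for KIAA0125).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "GENE_ALIASES",
    "canonical_symbol",
    "CellTypeMarkers",
    "DerivedScore",
    "MarkerSet",
    "load_marker_set",
    "bundled_markers",
]

# variant symbol -> canonical symbol (keys and values upper case)
GENE_ALIASES: dict[str, str] = {
    "PTRPC": "PTPRC",
    "FAM30A": "KIAA0125",
}


def canonical_symbol(symbol: str) -> str:
    """Upper-case a gene symbol and resolve known aliases."""
    s = str(symbol).strip().upper()
    return GENE_ALIASES.get(s, s)


@dataclass
class CellTypeMarkers:
    """Marker genes measuring one cell type."""

    name: str
    genes: list[str]
    single_gene: bool = False
    n_candidates: int | None = None
    mean_similarity: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.genes = [canonical_symbol(g) for g in self.genes]
        if not self.genes:
            raise ValueError(f"cell type {self.name!r} has no marker genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate marker genes for cell type {self.name!r}")
        if self.single_gene and len(self.genes) != 1:
            raise ValueError(f"{self.name!r} flagged single_gene but has {len(self.genes)} genes")


@dataclass
class DerivedScore:
    """A cell score defined as the difference of two other scores.

    The score is ``minuend − subtrahend`` on the log2 scale, i.e. the log2
    ratio of the two inferred abundances (e.g. CD4 = T-cells − CD8 T cells).
    """

    name: str
    minuend: str
    subtrahend: str
    n_candidates: int | None = None
    note: str = ""


@dataclass
class MarkerSet:
    """An ordered collection of cell types with their marker genes."""

    cell_types: list[CellTypeMarkers]
    derived_scores: list[DerivedScore] = field(default_factory=list)
    version: int | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.cell_types] + [d.name for d in self.derived_scores]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names in marker set")

    @property
    def cell_type_names(self) -> list[str]:
        return [c.name for c in self.cell_types]

    @property
    def all_genes(self) -> list[str]:
        """Unique marker genes across all cell types, in first-seen order."""
        seen: dict[str, None] = {}
        for ct in self.cell_types:
            for g in ct.genes:
                seen.setdefault(g)
        return list(seen)

    def __getitem__(self, name: str) -> CellTypeMarkers:
        for ct in self.cell_types:
            if ct.name == name:
                return ct
        raise KeyError(name)

    def __iter__(self):
        return iter(self.cell_types)

    def __len__(self) -> int:
        return len(self.cell_types)

    def subset(self, available_genes) -> "MarkerSet":
        """Restrict every cell type to the genes present in ``available_genes``.

        Cell types left without any marker are dropped; callers are expected
        to warn. Mirrors the convention used on reduced panels, where each
        score is the average of whatever marker genes the assay includes.
        """
        avail = {canonical_symbol(g) for g in available_genes}
        kept = []
        for ct in self.cell_types:
            genes = [g for g in ct.genes if g in avail]
            if genes:
                kept.append(
                    CellTypeMarkers(
                        ct.name, genes, ct.single_gene and len(genes) == 1,
                        ct.n_candidates, ct.mean_similarity, ct.note,
                    )
                )
        kept_names = {c.name for c in kept}
        derived = [
            d for d in self.derived_scores
            if d.minuend in kept_names and d.subtrahend in kept_names
        ]
        return MarkerSet(kept, derived, self.version)


def _from_mapping(doc: dict) -> MarkerSet:
    cell_types = [
        CellTypeMarkers(
            name=entry["name"],
            genes=list(entry["genes"]),
            single_gene=bool(entry.get("single_gene", False)),
            n_candidates=entry.get("n_candidates"),
            mean_similarity=entry.get("mean_similarity"),
            note=entry.get("note", ""),
        )
        for entry in doc["cell_types"]
    ]
    derived = [
        DerivedScore(
            name=entry["name"],
            minuend=entry["minuend"],
            subtrahend=entry["subtrahend"],
            n_candidates=entry.get("n_candidates"),
            note=entry.get("note", ""),
        )
        for entry in doc.get("derived_scores", [])
    ]
    return MarkerSet(cell_types, derived, version=doc.get("version"))


def load_marker_set(path) -> MarkerSet:
    """Load a marker set from a YAML/JSON mapping file.

    Accepts either the full schema (``cell_types:`` list of mappings) or the
    minimal shorthand ``{cell type: [gene, ...]}``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "cell_types" not in doc:
        doc = {
            "cell_types": [
                {"name": k, "genes": v, "single_gene": len(v) == 1}
                for k, v in doc.items()
            ]
        }
    return _from_mapping(doc)


def bundled_markers() -> MarkerSet:
    """The bundled TIL-60 marker set (60 genes, 14 cell types, CD4 derived)."""
    ref = importlib.resources.files("tilscore.data").joinpath("til60.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _from_mapping(doc)
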