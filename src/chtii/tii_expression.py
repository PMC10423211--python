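"""Single-cell expression evidence: is a candidate gene expressed in
tumor-infiltrating immune cells, and in which immune cell types?

Works on a barcoded sparse cell x gene count matrix with per-cell type
labels (MatrixMarket triplet plus label TSV).  A cell "expresses" a gene iff
its raw count is > 0 — presence/absence on raw counts, no normalization.
Two ratios are reported per gene: ``immune_fraction`` (immune-expressing /
total-expressing cells, the candidate-table-compatible ratio) and
``immune_expressing_fraction_of_immune`` (immune-expressing / all immune
cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

#: Default immune/non-immune call per cell-type label.  Covers this
#: package's synthetic vocabulary and the published breast-tumor
#: microenvironment atlas vocabulary (major cell types).
DEFAULT_IMMUNE_LABELS: dict[str, bool] = {
    # synthetic vocabulary
    "T-cell": True,
    "myeloid": True,
    "B-cell": True,
    "NK": True,
    "epithelial": False,
    "stromal": False,
    "endothelial": False,
    # breast-atlas major cell types
    "T-cells": True,
    "Myeloid": True,
    "B-cells": True,
    "Plasmablasts": True,
    "Cancer Epithelial": False,
    "Normal Epithelial": False,
    "CAFs": False,
    "PVL": False,
    "Endothelial": False,
}


@dataclass
class CellMatrix:
    """Sparse cell x gene counts with per-cell type labels."""

    cells: list[str]
    genes: list[str]
    counts: sparse.csc_matrix  # cells x genes
    cell_type: list[str]
    is_immune: dict[str, bool]

    def __post_init__(self):
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("count matrix shape does not match barcode/gene lists")
        if len(self.cell_type) != len(self.cells):
            raise ValueError("every cell must have a type label")
        unknown = sorted(set(self.cell_type) - set(self.is_immune))
        if unknown:
            raise ValueError(f"cell-type label(s) without immune call: {unknown}")
        self._gene_index = {g: j for j, g in enumerate(self.genes)}
        self._immune_mask = np.array([self.is_immune[t] for t in self.cell_type])

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def read_cell_matrix(
    mtx_path,
    barcodes_path,
    genes_path,
    celltypes_path,
    is_immune: dict[str, bool] | None = None,
) -> CellMatrix:
    """Load a MatrixMarket triplet (cells x genes) plus a cell-type TSV.

    ``barcodes`` and ``genes`` are one-entry-per-line TSVs aligned to matrix
    rows and columns; ``celltypes`` is a two-column TSV (barcode, label)
    joined on barcode.  A barcode present in the matrix but absent from the
    label file is a format error naming the first offending barcode.
    """
    counts = sparse.csc_matrix(spio.mmread(str(mtx_path)))
    if (counts.data < 0).any():
        raise ValueError("negative counts in matrix")
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    labels = pd.read_csv(celltypes_path, sep="\t", header=0)
    label_map = dict(zip(labels["barcode"].astype(str), labels["cell_type"].astype(str)))
    for bc in barcodes:
        if bc not in label_map:
            raise ValueError(f"barcode without cell-type label: {bc!r}")
    return CellMatrix(
        cells=barcodes,
        genes=genes,
        counts=counts,
        cell_type=[label_map[bc] for bc in barcodes],
        is_immune=dict(DEFAULT_IMMUNE_LABELS if is_immune is None else is_immune),
    )


def summarize_gene_expression(matrix: CellMatrix, gene: str) -> dict:
    """Expression summary for one gene.

    Returns total and immune expressing-cell counts, the immune fraction
    (immune-expressing / total-expressing; None when no cell expresses the
    gene), the fraction of immune cells expressing the gene, and the
    breakdown of immune expressing cells by cell-type label (sums to 1 when
    any immune cell expresses the gene).
    """
    if gene not in matrix._gene_index:
        raise KeyError(f"gene not in matrix: {gene!r}")
    col = matrix.counts[:, matrix._gene_index[gene]].toarray().ravel()
    expressing = col > 0
    immune_expressing = expressing & matrix._immune_mask
    n_expr = int(expressing.sum())
    n_immune_expr = int(immune_expressing.sum())
    breakdown: dict[str, float] = {}
    if n_immune_expr:
        types = pd.Series(matrix.cell_type)[immune_expressing]
        breakdown = (types.value_counts() / n_immune_expr).to_dict()
    n_immune_cells = int(matrix._immune_mask.sum())
    return {
        "gene": gene,
        "n_cells_expressing": n_expr,
        "n_immune_cells_expressing": n_immune_expr,
        "immune_fraction": (n_immune_expr / n_expr) if n_expr else None,
        "immune_expressing_fraction_of_immune": (
            n_immune_expr / n_immune_cells if n_immune_cells else None
        ),
        "celltype_breakdown": breakdown,
    }


def filter_expressed_in_immune(
    summaries: dict[str, dict], candidates: pd.DataFrame
) -> pd.DataFrame:
    """Retain candidate variants whose gene is expressed in >= 1 immune cell.

    *summaries* maps gene -> expression summary; every candidate gene must be
    summarized.
    """
    for gene in candidates["gene"].unique():
        if gene not in summaries:
            raise KeyError(f"candidate gene not summarized: {gene!r}")
    keep = [summaries[g]["n_immune_cells_expressing"] > 0 for g in candidates["gene"]]
    return candidates.loc[keep]


def celltype_composition(summaries: list[dict]) -> dict[str, float]:
    """Pool immune expressing-cell counts across genes into per-type fractions.

    Answers "which immune cell types express the candidate genes": counts of
    immune expressing cells per label, pooled over all summaries, normalized
    to sum to 1.  Raises on an all-zero pool.
    """
    if not summaries:
        raise ValueError("need at least one gene summary")
    pooled: dict[str, float] = {}
    for s in summaries:
        n = s["n_immune_cells_expressing"]
        for label, frac in s["celltype_breakdown"].items():
            pooled[label] = pooled.get(label, 0.0) + frac * n
    total = sum(pooled.values())
    if total == 0:
        raise ValueError("no immune expressing cells in any summary")
    return {label: count / total for label, count in pooled.items()}
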