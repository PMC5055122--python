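"""Cell- and gene-level quality filters for UMI count matrices.

Cells are retained when their total molecule count falls inside an
inclusive [min, max] window (removing broken cells below and putative
doublets above); genes detected at fewer than ``min_gene_total``
molecules across the whole dataset are discarded.  The pipeline applies
the cell filter first, so the gene totals used by the gene filter refer
to the post-QC dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class NoCellsPassQC(ValueError):
    """Raised when a cell filter would return an empty matrix."""


@dataclass
class QCThresholds:
    min_molecules: int = 2000
    max_molecules: int = 26000
    min_gene_total: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.min_molecules < self.max_molecules):
            raise ValueError("require 0 <= min_molecules < max_molecules")
        if self.min_gene_total < 0:
            raise ValueError("min_gene_total must be >= 0")


def filter_cells_by_molecules(
    matrix: ExpressionMatrix, thr: QCThresholds
) -> tuple[ExpressionMatrix, dict]:
    """Retain cells with min <= total molecules <= max (both inclusive).

    Returns the filtered matrix and a report with per-cell totals and
    the min/median/max of retained cells.
    """
    totals = matrix.cell_totals()
    keep = (totals >= thr.min_molecules) & (totals <= thr.max_molecules)
    if not keep.any():
        raise NoCellsPassQC(
            f"no cells pass QC: no total in [{thr.min_molecules}, {thr.max_molecules}]"
        )
    kept = totals[keep]
    report = {
        "cells_in": int(matrix.n_cells),
        "cells_out": int(keep.sum()),
        "totals": pd.Series(totals, index=matrix.cells),
        "retained_min": int(kept.min()),
        "retained_median": float(np.median(kept)),
        "retained_max": int(kept.max()),
    }
    return matrix.subset_cells(keep), report


def filter_low_count_genes(
    matrix: ExpressionMatrix, thr: QCThresholds
) -> tuple[ExpressionMatrix, dict]:
    """Drop genes with dataset-wide total < min_gene_total (strict)."""
    totals = matrix.gene_totals()
    keep = totals >= thr.min_gene_total
    report = {"genes_in": int(matrix.n_genes), "genes_out": int(keep.sum())}
    return matrix.subset_genes(keep), report


def drop_inconsistent_cells(
    matrix: ExpressionMatrix,
    labels_a: pd.Series,
    labels_b: pd.Series,
) -> ExpressionMatrix:
    """Optional hook: drop cells whose cluster assignment disagrees
    between two clusterings AND whose molecule total is below the
    dataset median.  Off by default in the pipeline; the assignment
    comparison is label-set agnostic (it tests whether the two leaf
    partitions put the cell in matching co-membership classes would be
    overkill — plain label disagreement after alignment is used).
    """
    a = labels_a.reindex(matrix.cells)
    b = labels_b.reindex(matrix.cells)
    # align label namespaces: map each a-label to its modal b-label
    modal = {la: b[a == la].mode().iloc[0] for la in a.dropna().unique()}
    disagree = np.array([modal.get(la) != lb for la, lb in zip(a, b)])
    low = matrix.cell_totals() < np.median(matrix.cell_totals())
    keep = ~(disagree & low)
    if not keep.any():
        raise NoCellsPassQC("no cells pass the consistency filter")
    return matrix.subset_cells(keep)


def run_qc(matrix: ExpressionMatrix, thr: QCThresholds) -> tuple[ExpressionMatrix, dict]:
    """Cell filter then gene filter, with a combined JSON-able report."""
    filtered, cell_report = filter_cells_by_molecules(matrix, thr)
    filtered, gene_report = filter_low_count_genes(filtered, thr)
    report = {
        "cells_in": cell_report["cells_in"],
        "cells_out": cell_report["cells_out"],
        "median_molecules": cell_report["retained_median"],
        **gene_report,
    }
    return filtered, report
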