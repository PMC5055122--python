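"""Expression-matrix container and on-disk formats.

The pipeline operates on UMI count matrices laid out genes x cells, the
orientation in which biclustering and marker fitting are expressed.  The
container is deliberately light: a dense integer array plus gene/cell
identifiers and a per-cell metadata table.  Matrices of the size this
package targets (a few thousand cells by a few thousand genes) are cheap
to hold dense.

On disk a matrix is either a MatrixMarket coordinate file with
``genes.tsv`` / ``cells.tsv`` sidecars, or a single dense TSV with genes
in rows and cell identifiers as the header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """Genes x cells UMI count matrix with identifiers and cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer array, shape ``(n_genes, n_cells)``.
    genes
        Gene identifiers, length ``n_genes``, unique.
    cells
        Cell identifiers, length ``n_cells``, unique.
    cell_meta
        Optional per-cell table (age, dataset, cluster label, ...) indexed
        by cell identifier.
    """

    counts: np.ndarray
    genes: pd.Index
    cells: pd.Index
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if len(self.genes) != self.counts.shape[0]:
            raise ValueError("gene identifiers do not match matrix rows")
        if len(self.cells) != self.counts.shape[1]:
            raise ValueError("cell identifiers do not match matrix columns")
        if self.genes.has_duplicates or self.cells.has_duplicates:
            raise ValueError("gene and cell identifiers must be unique")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cells)
        else:
            self.cell_meta = self.cell_meta.reindex(self.cells)

    # -- basic geometry -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total molecules per cell."""
        return self.counts.sum(axis=0)

    def gene_totals(self) -> np.ndarray:
        """Total molecules per gene across all cells."""
        return self.counts.sum(axis=1)

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._resolve(mask_or_ids, self.cells)
        return ExpressionMatrix(
            self.counts[:, idx],
            self.genes,
            self.cells[idx],
            self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        idx = self._resolve(mask_or_ids, self.genes)
        return ExpressionMatrix(
            self.counts[idx, :], self.genes[idx], self.cells, self.cell_meta
        )

    @staticmethod
    def _resolve(mask_or_ids, index: pd.Index) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            if arr.shape != (len(index),):
                raise ValueError("boolean mask has wrong length")
            return np.flatnonzero(arr)
        if np.issubdtype(arr.dtype, np.integer):
            return arr
        locs = index.get_indexer(arr)
        if (locs < 0).any():
            missing = list(np.asarray(arr)[locs < 0][:5])
            raise KeyError(f"identifiers not found: {missing}")
        return locs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.cells)

    # -- IO ---------------------------------------------------------------
    def write_mtx(self, directory: os.PathLike | str) -> None:
        """Write matrix.mtx (1-based triplets) + genes.tsv / cells.tsv."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(d / "matrix.mtx", scipy.sparse.coo_matrix(self.counts))
        pd.Series(self.genes).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
        meta = self.cell_meta.copy()
        meta.insert(0, "cell", self.cells)
        meta.to_csv(d / "cells.tsv", sep="\t", index=False)

    @classmethod
    def read_mtx(cls, directory: os.PathLike | str) -> "ExpressionMatrix":
        d = Path(directory)
        counts = scipy.io.mmread(d / "matrix.mtx").toarray().astype(np.int64)
        genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0]
        cells_df = pd.read_csv(d / "cells.tsv", sep="\t")
        cells = pd.Index(cells_df["cell"].to_numpy())
        meta = cells_df.drop(columns="cell")
        meta.index = cells
        return cls(counts, pd.Index(genes.to_numpy()), cells, meta)

    def write_tsv(self, path: os.PathLike | str) -> None:
        """Dense TSV, genes in rows, header = cell identifiers."""
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: os.PathLike | str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=np.int64), df.index, pd.Index(df.columns))
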