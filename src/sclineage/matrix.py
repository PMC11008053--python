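"""Genes x cells UMI count matrix with gene and cell metadata.

The on-disk format is the MatrixMarket trio used by most droplet pipelines:
``matrix.mtx`` (1-based coordinate format, genes as rows), ``genes.tsv`` and
``cells.tsv``.  Cell metadata (timepoint, true lineage when known) lives in
extra columns of ``cells.tsv``; the mitochondrial mask is derived from a gene
name prefix (default ``MT-``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class CountMatrix:
    """UMI counts (genes x cells) plus per-gene and per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes as rows, cells as columns.  Stored
        dense internally; inputs may be sparse.
    genes
        Per-gene table indexed by gene id.  A boolean ``mito`` column marks
        mitochondrial genes.
    cells
        Per-cell table indexed by cell id.  May carry ``timepoint``,
        ``lineage``, ``doublet`` columns.
    """

    counts: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if sparse.issparse(self.counts):
            self.counts = np.asarray(self.counts.todense())
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for frame, what in ((self.genes, "gene"), (self.cells, "cell")):
            if frame.index.has_duplicates:
                raise ValueError(f"duplicate {what} ids")
        if "mito" not in self.genes.columns:
            self.genes = self.genes.assign(
                mito=self.genes.index.str.startswith("MT-")
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    @property
    def mito_mask(self) -> np.ndarray:
        return self.genes["mito"].to_numpy(dtype=bool)

    def total_umi(self) -> np.ndarray:
        """Total UMI per cell."""
        return self.counts.sum(axis=0)

    def genes_detected(self) -> np.ndarray:
        """Number of genes with at least one UMI, per cell."""
        return (self.counts > 0).sum(axis=0)

    def mito_ratio(self) -> np.ndarray:
        """Fraction of each cell's UMIs falling in mitochondrial genes."""
        tot = self.total_umi().astype(float)
        mito = self.counts[self.mito_mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(tot > 0, mito / np.maximum(tot, 1e-300), 0.0)
        return r

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, keep) -> "CountMatrix":
        """Return a new matrix restricted to ``keep`` (mask or cell ids)."""
        idx = self._as_indexer(keep, self.cells.index)
        return CountMatrix(self.counts[:, idx], self.genes.copy(), self.cells.iloc[idx].copy())

    def subset_genes(self, keep) -> "CountMatrix":
        idx = self._as_indexer(keep, self.genes.index)
        return CountMatrix(self.counts[idx, :], self.genes.iloc[idx].copy(), self.cells.copy())

    @staticmethod
    def _as_indexer(keep, index: pd.Index) -> np.ndarray:
        keep = np.asarray(keep)
        if keep.dtype == bool:
            if keep.shape[0] != len(index):
                raise ValueError("boolean mask length mismatch")
            return np.flatnonzero(keep)
        return index.get_indexer(keep)

    # -- IO ---------------------------------------------------------------
    def write_mtx(self, outdir: str | Path) -> None:
        """Write the matrix.mtx / genes.tsv / cells.tsv trio."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(outdir / "matrix.mtx", sparse.coo_matrix(self.counts))
        self.genes.to_csv(outdir / "genes.tsv", sep="\t", index_label="gene")
        self.cells.to_csv(outdir / "cells.tsv", sep="\t", index_label="cell")

    @classmethod
    def read_mtx(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        counts = np.asarray(spio.mmread(indir / "matrix.mtx").todense())
        genes = pd.read_csv(indir / "genes.tsv", sep="\t", index_col="gene")
        cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col="cell")
        return cls(counts.astype(np.int64), genes, cells)
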