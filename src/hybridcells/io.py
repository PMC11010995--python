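"""Count-matrix container and Matrix Market / CSV input-output.

The universal in-memory object is :class:`CountMatrix`: a sparse
cells x genes matrix with cell and gene identifiers.  On disk the
canonical representation is the CellRanger-style Matrix Market trio
(``matrix.mtx`` with genes as rows, ``barcodes.tsv``, ``features.tsv``)
plus a plain cell-metadata CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "write_mtx_dir", "read_mtx_dir"]


@dataclass
class CountMatrix:
    """Sparse nonnegative cells x genes matrix with identifiers.

    Parameters
    ----------
    X
        ``(n_cells, n_genes)`` sparse matrix (stored as CSR).
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    """

    X: sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    _gene_index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def gene_column(self, gene: str) -> np.ndarray:
        """Dense vector of the named gene's values across cells."""
        try:
            j = self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None
        return np.asarray(self.X[:, j].todense()).ravel()

    def gene_indices(self, genes) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(self.X[idx], self.cell_ids[idx], self.gene_ids)

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_indices(genes)
        return CountMatrix(self.X[:, idx], self.cell_ids, self.gene_ids[idx])

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.X.copy(), self.cell_ids.copy(), self.gene_ids.copy())


def write_mtx_dir(path, matrix: CountMatrix) -> None:
    """Write a CellRanger-style trio: matrix.mtx (genes x cells),
    barcodes.tsv, features.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.csc_matrix(matrix.X.T))
    (path / "barcodes.tsv").write_text("\n".join(map(str, matrix.cell_ids)) + "\n")
    (path / "features.tsv").write_text("\n".join(map(str, matrix.gene_ids)) + "\n")


def read_mtx_dir(path) -> CountMatrix:
    """Read a matrix.mtx + barcodes.tsv + features.tsv trio."""
    path = Path(path)
    mtx = path / "matrix.mtx"
    if not mtx.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    X = sp.csr_matrix(scipy.io.mmread(str(mtx)).T)
    cells = pd.read_csv(path / "barcodes.tsv", header=None)[0].astype(str).to_numpy()
    genes = pd.read_csv(path / "features.tsv", header=None, sep="\t")[0].astype(str).to_numpy()
    return CountMatrix(X, cells, genes)
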