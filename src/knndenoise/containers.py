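"""Core in-memory containers shared across the package.

Matrices are always oriented cells x genes.  Values may be dense numpy
arrays or scipy sparse matrices; operations preserve sparsity where that
is meaningful (preprocessing) and densify where it is not (denoised
output, since weighted averaging destroys the zero pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NeighborGraph",
    "TransitionMatrix",
    "as_dense",
]


def as_dense(values) -> np.ndarray:
    """Return ``values`` as a dense float ndarray."""
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


def _check_labels(labels: Sequence[str], n: int, what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(
            f"{what} label count ({len(labels)}) does not match matrix dimension ({n})"
        )
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels are not allowed")
    return labels


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with labels.

    Parameters
    ----------
    values : ndarray or sparse matrix
        Nonnegative expression values, cells in rows, genes in columns.
    cell_ids, gene_ids : sequence of str
        Unique row / column labels.
    raw_counts : bool
        True when the matrix holds raw (integer) UMI counts, False for
        normalized / transformed values.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    raw_counts: bool = False

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if n == 0 or m == 0:
            raise ValueError("expression matrix must be nonempty")
        self.cell_ids = _check_labels(self.cell_ids, n, "cell")
        self.gene_ids = _check_labels(self.gene_ids, m, "gene")

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def to_dense(self) -> np.ndarray:
        return as_dense(self.values)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.cell_ids), list(self.gene_ids), self.raw_counts
        )

    def cell_totals(self) -> np.ndarray:
        """Total counts (or values) per cell."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def require_counts(self, op: str) -> None:
        """Raise unless the matrix holds nonnegative integer counts."""
        data = self.values.data if sp.issparse(self.values) else self.values
        data = np.asarray(data)
        if data.size and data.min() < 0:
            raise ValueError(f"{op}: counts must be nonnegative")
        if not np.issubdtype(data.dtype, np.integer):
            if data.size and np.any(data != np.round(data)):
                raise ValueError(f"{op}: expected integer counts, got non-integer values")

    def require_nonnegative(self, op: str) -> None:
        data = self.values.data if sp.issparse(self.values) else self.values
        if np.asarray(data).size and np.asarray(data).min() < 0:
            raise ValueError(f"{op}: negative entries are not allowed")

    def subset(self, cell_mask=None, gene_mask=None) -> "ExpressionMatrix":
        """Row/column subset preserving input order (order-stable)."""
        vals = self.values
        cells = self.cell_ids
        genes = self.gene_ids
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            vals = vals[cell_mask]
            cells = [c for c, keep in zip(cells, cell_mask) if keep] if cell_mask.dtype == bool else [cells[i] for i in cell_mask]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            vals = vals[:, gene_mask]
            genes = [g for g, keep in zip(genes, gene_mask) if keep] if gene_mask.dtype == bool else [genes[i] for i in gene_mask]
        return ExpressionMatrix(vals, cells, genes, self.raw_counts)

    @classmethod
    def from_array(cls, values, raw_counts: bool = False,
                   cell_ids=None, gene_ids=None) -> "ExpressionMatrix":
        """Wrap a bare array, generating default labels if absent."""
        n, m = values.shape
        if cell_ids is None:
            cell_ids = [f"cell_{i}" for i in range(n)]
        if gene_ids is None:
            gene_ids = [f"gene_{j}" for j in range(m)]
        return cls(values, cell_ids, gene_ids, raw_counts)

    @classmethod
    def from_dataframe(cls, df, raw_counts: bool = False) -> "ExpressionMatrix":
        """Build from a pandas DataFrame (index = cells, columns = genes)."""
        return cls(df.to_numpy(), list(df.index), list(df.columns), raw_counts)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.to_dense(), index=self.cell_ids, columns=self.gene_ids)


@dataclass
class NeighborGraph:
    """Per-cell k-nearest-neighbor graph.

    ``distances`` holds the asymmetric kNN distance matrix (u nonzeros
    per row, self excluded); ``connectivities`` the fuzzy-union
    symmetrized affinities in [0, 1].
    """

    distances: sp.csr_matrix
    connectivities: sp.csr_matrix
    n_neighbors: int
    metric: str = "euclidean"

    @property
    def n_cells(self) -> int:
        return self.distances.shape[0]


@dataclass
class TransitionMatrix:
    """Nonnegative cell x cell weight matrix used for graph smoothing."""

    weights: np.ndarray | sp.spmatrix
    mode: str = "distances"
    alpha: float = 1.0
    is_right_stochastic: bool = False
    has_zero_diagonal: bool = False

    def __post_init__(self) -> None:
        n, m = self.weights.shape
        if n != m:
            raise ValueError("transition matrix must be square")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def diagonal(self) -> np.ndarray:
        if sp.issparse(self.weights):
            return self.weights.diagonal()
        return np.diag(self.weights)

    def copy(self) -> "TransitionMatrix":
        return replace(self, weights=self.weights.copy())
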