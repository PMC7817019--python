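"""Count-matrix preprocessing: filtering, depth normalization, FTT.

The pipeline applied to raw UMI counts before graph construction is

    (i)   drop cells below explicit expressed-gene / total-count
          thresholds, then clip the extreme tails of the total-count
          distribution (0.5th percentile per tail by default);
    (ii)  drop genes expressed in no more than ``min_cells`` cells;
    (iii) scale every cell to the median total count;
    (iv)  apply the Freeman-Tukey transform sqrt(x) + sqrt(x+1) - 1,
          which stabilizes the variance of Poisson counts at ~1 while
          mapping zero to zero exactly (sparsity preserved).

All steps preserve sparse storage and row/column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix

__all__ = [
    "FilterSpec",
    "filter_cells",
    "filter_genes",
    "median_normalize",
    "freeman_tukey",
    "preprocess_counts",
]


@dataclass
class FilterSpec:
    """Explicit cell-filtering thresholds.

    ``clip_percentile`` is the fraction clipped from *each* tail of the
    per-cell total-count distribution (default 0.005, i.e. the top and
    bottom 0.5 percentile).
    """

    min_genes_per_cell: int = 0
    min_counts_per_cell: int = 0
    clip_percentile: float = 0.005
    min_cells_per_gene: int = 10

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_counts_per_cell, self.min_cells_per_gene) < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not 0.0 <= self.clip_percentile < 0.5:
            raise ValueError("clip_percentile must lie in [0, 0.5)")


def _expressed_per_cell(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (np.asarray(values) > 0).sum(axis=1)


def filter_cells(X: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Apply threshold filters then percentile clipping to cells.

    Cells are retained when their expressed-gene count exceeds
    ``min_genes_per_cell`` and their total count exceeds
    ``min_counts_per_cell``; of the survivors, cells whose totals fall
    strictly below the ``clip_percentile`` quantile or strictly above
    the ``1 - clip_percentile`` quantile are then removed.
    """
    X.require_counts("filter_cells")
    totals = X.cell_totals()
    expressed = _expressed_per_cell(X.values)

    mask = (expressed > spec.min_genes_per_cell) & (totals > spec.min_counts_per_cell)
    if not mask.any():
        bad = (
            "min_genes_per_cell"
            if not (expressed > spec.min_genes_per_cell).any()
            else "min_counts_per_cell"
        )
        raise ValueError(f"filter_cells: empty result — every cell fails threshold {bad!r}")

    if spec.clip_percentile > 0:
        kept = totals[mask]
        lo = np.quantile(kept, spec.clip_percentile)
        hi = np.quantile(kept, 1.0 - spec.clip_percentile)
        mask &= (totals >= lo) & (totals <= hi)
        if not mask.any():
            raise ValueError(
                "filter_cells: empty result — clip_percentile "
                f"{spec.clip_percentile} removed all remaining cells"
            )
    return X.subset(cell_mask=mask)


def filter_genes(X: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Keep genes expressed (count > 0) in strictly more than ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    if sp.issparse(X.values):
        support = np.asarray((X.values > 0).sum(axis=0)).ravel()
    else:
        support = (np.asarray(X.values) > 0).sum(axis=0)
    mask = support > min_cells
    if not mask.any():
        raise ValueError(
            f"filter_genes: empty result — no gene is expressed in more than {min_cells} cells"
        )
    return X.subset(gene_mask=mask)


def median_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell so its total equals the median cell total.

    Raises if any cell has zero total; filter cells first.
    """
    totals = X.cell_totals()
    if np.any(totals <= 0):
        idx = int(np.argmin(totals))
        raise ValueError(
            f"median_normalize: cell {X.cell_ids[idx]!r} has zero total count; "
            "run cell filtering before normalizing"
        )
    median = np.median(totals)
    scale = median / totals
    if sp.issparse(X.values):
        vals = sp.diags(scale) @ X.values.tocsr()
    else:
        vals = np.asarray(X.values, dtype=float) * scale[:, None]
    return ExpressionMatrix(vals, list(X.cell_ids), list(X.gene_ids), raw_counts=False)


def freeman_tukey_array(x):
    """Elementwise sqrt(x) + sqrt(x + 1) - 1 on an ndarray."""
    x = np.asarray(x, dtype=float)
    return np.sqrt(x) + np.sqrt(x + 1.0) - 1.0


def freeman_tukey(X: ExpressionMatrix) -> ExpressionMatrix:
    """Freeman-Tukey transform with the -1 shift that preserves zeros.

    Zeros map exactly to zero, so the sparse support set is unchanged.
    """
    X.require_nonnegative("freeman_tukey")
    if sp.issparse(X.values):
        vals = X.values.tocsr().copy().astype(float)
        vals.data = freeman_tukey_array(vals.data)
    else:
        vals = freeman_tukey_array(X.values)
    return ExpressionMatrix(vals, list(X.cell_ids), list(X.gene_ids), raw_counts=False)


def preprocess_counts(
    X: ExpressionMatrix,
    spec: FilterSpec | None = None,
    transform: str = "ftt",
) -> ExpressionMatrix:
    """Full preprocessing pipeline: filter -> median normalize -> FTT.

    ``transform`` may be ``"ftt"`` or ``"none"`` (stop after depth
    normalization).
    """
    if spec is None:
        spec = FilterSpec()
    if transform not in ("ftt", "none"):
        raise ValueError("transform must be 'ftt' or 'none'")
    X = filter_cells(X, spec)
    X = filter_genes(X, spec.min_cells_per_gene)
    X = median_normalize(X)
    if transform == "ftt":
        X = freeman_tukey(X)
    return X
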