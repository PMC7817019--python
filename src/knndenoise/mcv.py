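"""Molecular cross-validation for PCA rank selection on raw counts.

Each observed count c is split into two statistically independent
halves by binomial thinning: c_J ~ Binomial(c, p), c_Jc = c - c_J.
Because the halves are independent Poisson draws around the same
underlying rates, a model fitted on one half can be scored against the
other without any ground truth: reconstruction at rank r of the first
half is compared to the (depth-matched) second half under squared
loss, and the loss-minimizing rank is selected.  Overfit ranks chase
noise in the fitting half and are punished by the held-out half, so
the loss curve is U-shaped around the true rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, as_dense
from .preprocess import freeman_tukey, median_normalize

__all__ = ["CountSplit", "MCVResult", "binomial_split", "mcv_rank_select"]


@dataclass
class CountSplit:
    X_J: ExpressionMatrix
    X_Jc: ExpressionMatrix
    split_fraction: float
    seed: int


@dataclass
class MCVResult:
    rank: int
    rank_grid: list[int]
    loss: np.ndarray          # loss used for selection
    loss_raw: np.ndarray      # count-space loss
    loss_transformed: np.ndarray | None  # FTT-space loss (None if undefined)
    normalized: bool

    def loss_curve(self):
        import pandas as pd

        return pd.DataFrame(
            {"rank": self.rank_grid, "loss_raw": self.loss_raw,
             "loss_transformed": self.loss_transformed
             if self.loss_transformed is not None else np.nan}
        )


def binomial_split(X: ExpressionMatrix, p: float = 0.5, seed: int = 0) -> CountSplit:
    """Binomial thinning of every count into two conserving halves."""
    if not 0.0 < p < 1.0:
        raise ValueError("split fraction p must lie strictly between 0 and 1")
    X.require_counts("binomial_split")
    rng = np.random.default_rng(seed)
    if sp.issparse(X.values):
        V = X.values.tocsr().copy()
        counts = np.asarray(np.round(V.data), dtype=np.int64)
        half = rng.binomial(counts, p)
        A = V.copy()
        A.data = half.astype(V.data.dtype)
        B = V.copy()
        B.data = (counts - half).astype(V.data.dtype)
        A.eliminate_zeros()
        B.eliminate_zeros()
    else:
        counts = np.asarray(np.round(X.values), dtype=np.int64)
        A = rng.binomial(counts, p)
        B = counts - A
    mk = lambda vals: ExpressionMatrix(vals, list(X.cell_ids), list(X.gene_ids), raw_counts=True)
    return CountSplit(mk(A), mk(B), p, seed)


def _transformed(half: ExpressionMatrix) -> np.ndarray:
    return freeman_tukey(median_normalize(half)).to_dense()


def _rank_reconstructions(train: np.ndarray, ranks: list[int]):
    """Centered-PCA reconstructions of ``train`` at each rank."""
    mean = train.mean(axis=0, keepdims=True)
    centered = train - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    for r in ranks:
        yield r, mean + (U[:, :r] * s[:r]) @ Vt[:r]


def mcv_rank_select(
    split: CountSplit, rank_grid, normalize: bool = True
) -> tuple[int, MCVResult]:
    """Select the PCA rank by cross-half reconstruction loss.

    With ``normalize=True`` the loss is computed in the transformed
    space used by the denoising pipeline (median normalization + FTT
    applied to each half independently); otherwise in count space with
    the held-out half rescaled by p / (1 - p) to match expected depth.
    Both loss curves are always reported.

    Returns ``(rank, MCVResult)``.
    """
    ranks = sorted(set(int(r) for r in rank_grid))
    if not ranks:
        raise ValueError("rank_grid must be nonempty")
    A_counts = as_dense(split.X_J.values).astype(float)
    B_counts = as_dense(split.X_Jc.values).astype(float)
    max_rank = min(A_counts.shape)
    if max(ranks) > max_rank:
        raise ValueError(f"max rank {max(ranks)} exceeds min matrix dimension {max_rank}")
    if A_counts.sum() == 0 or B_counts.sum() == 0:
        raise ValueError("mcv_rank_select: a split half is all zeros; increase depth")

    p = split.split_fraction
    scale = p / (1.0 - p)
    target_raw = B_counts * scale

    loss_raw = np.empty(len(ranks))
    for i, (r, recon) in enumerate(_rank_reconstructions(A_counts, ranks)):
        loss_raw[i] = np.mean((recon - target_raw) ** 2)

    loss_tr = None
    if np.all(A_counts.sum(axis=1) > 0) and np.all(B_counts.sum(axis=1) > 0):
        A_t = _transformed(split.X_J)
        target_t = _transformed(split.X_Jc)
        loss_tr = np.empty(len(ranks))
        for i, (r, recon) in enumerate(_rank_reconstructions(A_t, ranks)):
            loss_tr[i] = np.mean((recon - target_t) ** 2)
    elif normalize:
        raise ValueError(
            "mcv_rank_select: a cell has a zero-total half; transformed-space "
            "loss is undefined — filter cells or use normalize=False"
        )

    loss = loss_tr if normalize else loss_raw
    rank = ranks[int(np.argmin(loss))]
    return rank, MCVResult(rank, ranks, loss, loss_raw, loss_tr, normalize)
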