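"""Evaluation metrics for denoising benchmarks."""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ExpressionMatrix, as_dense
from .simulate import GroundTruth

__all__ = ["within_group_mean_correlation", "mse_to_truth"]


def within_group_mean_correlation(X, groups) -> float:
    """Mean Pearson correlation over all within-group cell pairs.

    Correlations are computed between gene-expression vectors of cell
    pairs known to belong to the same group and averaged over all such
    pairs, pooled across groups.  Zero-variance cells cannot enter a
    Pearson correlation and are skipped with a warning.
    """
    dense = X.to_dense() if isinstance(X, ExpressionMatrix) else as_dense(X)
    groups = np.asarray(groups)
    if groups.shape[0] != dense.shape[0]:
        raise ValueError("label count must equal cell count")

    total = 0.0
    n_pairs = 0
    n_skipped = 0
    for g in np.unique(groups):
        block = dense[groups == g]
        if block.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 cells")
        centered = block - block.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        ok = norms > 0
        skipped_here = int((~ok).sum())
        if skipped_here:
            n_skipped += skipped_here
        Z = centered[ok] / norms[ok][:, None]
        k = Z.shape[0]
        if k < 2:
            continue
        corr = Z @ Z.T
        iu = np.triu_indices(k, 1)
        total += corr[iu].sum()
        n_pairs += iu[0].size
    if n_skipped:
        warnings.warn(
            f"within_group_mean_correlation: skipped {n_skipped} zero-variance "
            "cell(s)", UserWarning,
        )
    if n_pairs == 0:
        raise ValueError("no valid within-group pairs")
    return float(total / n_pairs)


def mse_to_truth(
    X,
    truth: GroundTruth,
    transform=None,
    target_total: float | None = None,
) -> float:
    """Mean squared distance of each cell to its group's true mean.

    ``target_total`` rescales every true profile to that row total
    first (mirroring depth normalization of the observed data);
    ``transform`` (e.g. the Freeman-Tukey array transform) is then
    applied to the true means so the comparison happens in the same
    space as ``X``.
    """
    dense = X.to_dense() if isinstance(X, ExpressionMatrix) else as_dense(X)
    targets = truth.true_means[truth.group_labels].astype(float)
    if targets.shape != dense.shape:
        raise ValueError(
            f"dimension mismatch: data {dense.shape} vs truth {targets.shape}"
        )
    if target_total is not None:
        row = targets.sum(axis=1, keepdims=True)
        targets = targets * (target_total / row)
    if transform is not None:
        targets = transform(targets)
    diff = dense - targets
    return float(np.mean(diff * diff))
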