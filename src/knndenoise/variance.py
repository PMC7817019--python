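"""Variance-structure diagnostics via the standardized SVD.

Columns are standardized to mean 0 / population standard deviation 1,
singular values are computed, and values at or below the numerical-rank
cutoff

    s <= max(S) * max(m, n) * eps     (eps = float32 machine epsilon)

are treated as zero and excluded.  The relative variance of each
retained component is eta_i^2 = s_i^2 / sum(s^2), and its condition
number kappa_i = s_i / s_min.  The number of components needed to reach
a cumulative variance fraction (e.g. 90%) is the oversmoothing
diagnostic: heavily smoothed data collapse onto a handful of
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, as_dense

__all__ = [
    "VarianceSpectrum",
    "standardize",
    "spectrum",
    "components_for_fraction",
]

#: float32 machine epsilon, the default rank-cutoff precision
#: regardless of storage dtype.
RANK_EPSILON = float(np.finfo(np.float32).eps)


@dataclass
class VarianceSpectrum:
    singular_values: np.ndarray   # retained, nonincreasing
    relative_variance: np.ndarray  # eta^2, sums to 1
    cumulative: np.ndarray
    condition_numbers: np.ndarray
    numerical_rank: int
    rank_epsilon: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(1, self.numerical_rank + 1),
                "singular_value": self.singular_values,
                "eta2": self.relative_variance,
                "cumulative": self.cumulative,
                "kappa": self.condition_numbers,
            }
        )


def standardize(X) -> np.ndarray:
    """Column-standardize to mean 0, population (divisor n) std 1.

    Zero-variance columns are dropped with a warning; all-constant
    input is an error.
    """
    dense = X.to_dense() if isinstance(X, ExpressionMatrix) else as_dense(X)
    dense = np.asarray(dense, dtype=float)
    mean = dense.mean(axis=0)
    std = dense.std(axis=0)  # population
    keep = std > 0
    if not keep.any():
        raise ValueError("standardize: every column is constant")
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(
            f"standardize: dropped {dropped} zero-variance column(s)", UserWarning
        )
    return (dense[:, keep] - mean[keep]) / std[keep]


def spectrum(X, rank_epsilon: float = RANK_EPSILON) -> VarianceSpectrum:
    """Variance spectrum of the standardized matrix."""
    Z = standardize(X)
    m, n = Z.shape
    if max(m, n) <= 2000:
        s = np.linalg.svd(Z, compute_uv=False)
    else:
        from sklearn.utils.extmath import randomized_svd

        k = min(min(m, n), 1000)
        _, s, _ = randomized_svd(Z, n_components=k, random_state=0)
        s = np.sort(s)[::-1]
    cutoff = s.max() * max(m, n) * rank_epsilon
    retained = s[s > cutoff]
    if retained.size == 0:
        retained = s[:1]
    power = retained**2
    eta2 = power / power.sum()
    return VarianceSpectrum(
        singular_values=retained,
        relative_variance=eta2,
        cumulative=np.cumsum(eta2),
        condition_numbers=retained / retained[-1],
        numerical_rank=int(retained.size),
        rank_epsilon=rank_epsilon,
    )


def components_for_fraction(spec: VarianceSpectrum, fraction: float) -> int:
    """Smallest component count whose cumulative eta^2 reaches ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    # absorb floating rounding at the top of the curve
    idx = int(np.searchsorted(spec.cumulative, fraction - 1e-12))
    return min(idx + 1, spec.numerical_rank)
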