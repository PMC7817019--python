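"""Self-supervised diffusion objective and denoising.

A right-stochastic transition matrix M is turned into a leave-self-out
predictor by the invariant mapping s(.) (zero diagonal, rows
renormalized).  Diffusion deepens the neighborhood:

    B_1 = M,   B_n = s(B_{n-1}) s(M)

and the prediction at depth n is s(B_n) X, whose entry (k, j) is a
weighted average of gene j over all cells except k.  Because the
predictor never sees the value it predicts, the mean squared error

    MSE_n = || s(B_n) X - X ||^2 / (cells * genes)

is an unbiased self-supervised objective: it decreases while smoothing
removes noise and increases once smoothing destroys signal.  The
``run2best`` rule stops at the first local minimum; ``full_scan`` maps
the whole trace.  The denoised matrix is X* = s(B_{n*}) X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, TransitionMatrix, as_dense
from .graph import (
    build_knn,
    deself_weights,
    pca_embed,
    transition_from_graph,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseConfig",
    "ObjectiveTrace",
    "DenoiseResult",
    "GridRecord",
    "GridSearchResult",
    "predict",
    "mse",
    "diffuse_objective",
    "denoise",
    "no_reset_variant",
    "grid_search",
    "smoothing_operator",
]

_ROW_SUM_TOL = 1e-8


@dataclass
class DenoiseConfig:
    """One hyperparameter configuration of the smoother."""

    n_components: int = 50
    n_neighbors: int = 50
    mode: str = "distances"
    alpha: float = 1.0
    max_iterations: int = 20
    stop_rule: str = "run2best"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.n_components < 1 or self.n_neighbors < 1:
            raise ValueError("n_components and n_neighbors must be positive")
        if self.mode not in ("distances", "connectivities"):
            raise ValueError("mode must be 'distances' or 'connectivities'")
        if self.stop_rule not in ("run2best", "full_scan"):
            raise ValueError("stop_rule must be 'run2best' or 'full_scan'")


@dataclass
class ObjectiveTrace:
    """Per-iteration self-supervised MSE for one configuration.

    ``mse_per_iteration[i]`` is the MSE at diffusion depth n = i + 1;
    ``optimal_iteration`` is the 1-based argmin of the recorded trace
    (first occurrence).
    """

    mse_per_iteration: np.ndarray
    optimal_iteration: int
    config: DenoiseConfig | None = None
    truncated: bool = False  # s(.) became undefined before max_iterations

    @property
    def optimal_mse(self) -> float:
        return float(self.mse_per_iteration[self.optimal_iteration - 1])

    def __len__(self) -> int:
        return len(self.mse_per_iteration)


@dataclass
class DenoiseResult:
    """Denoised matrix together with the trace and operator that made it."""

    denoised: ExpressionMatrix
    trace: ObjectiveTrace
    transition: TransitionMatrix
    n_iterations: int


@dataclass
class GridRecord:
    mode: str
    n_neighbors: int
    n_components: int
    optimal_iteration: int
    mse: float
    trace: ObjectiveTrace


@dataclass
class GridSearchResult:
    """All grid evaluations plus the global best.

    Ties on MSE are broken toward fewer PCs, then fewer neighbors, then
    the distances mode.
    """

    records: list[GridRecord]
    best: GridRecord
    skipped: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "iteration": r.optimal_iteration,
                    "mode": r.mode,
                    "neighbors": r.n_neighbors,
                    "pcs": r.n_components,
                    "MSE": r.mse,
                }
                for r in self.records
            ]
        )


def _values(X) -> np.ndarray | sp.spmatrix:
    return X.values if isinstance(X, ExpressionMatrix) else X


def _check_invariant_operator(P, where: str) -> None:
    diag = P.diagonal() if sp.issparse(P) else np.diag(P)
    if np.max(np.abs(diag)) > 1e-12:
        raise ValueError(f"{where}: operator diagonal must be zero (invariance violated)")
    sums = np.asarray(P.sum(axis=1)).ravel()
    if np.max(np.abs(sums - 1.0)) > _ROW_SUM_TOL:
        raise ValueError(f"{where}: operator rows must sum to 1")


def predict(P, X) -> np.ndarray:
    """Leave-self-out prediction P X.

    ``P`` must be right-stochastic with a zero diagonal; entry (k, j)
    of the result is the weighted average of gene j over all cells
    other than k.
    """
    P_w = P.weights if isinstance(P, TransitionMatrix) else P
    Xv = _values(X)
    if P_w.shape[1] != Xv.shape[0]:
        raise ValueError("P and X are not conformable")
    _check_invariant_operator(P_w, "predict")
    out = P_w @ Xv
    return as_dense(out)


def mse(X_hat, X) -> float:
    """Mean squared difference over all matrix entries."""
    A = _values(X_hat)
    B = _values(X)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    if sp.issparse(A) or sp.issparse(B):
        diff = (A - B) if not sp.issparse(A) else (A - B)
        if sp.issparse(diff):
            return float(diff.multiply(diff).sum() / (diff.shape[0] * diff.shape[1]))
        diff = np.asarray(diff)
        return float(np.mean(diff * diff))
    diff = A - B
    return float(np.mean(diff * diff))


def _check_stochastic(M_w, where: str) -> None:
    sums = np.asarray(M_w.sum(axis=1)).ravel()
    if np.max(np.abs(sums - 1.0)) > _ROW_SUM_TOL:
        raise ValueError(f"{where}: transition matrix must be right-stochastic; "
                         "apply row_normalize first")


def _maybe_densify(A):
    # products of kNN operators fill in rapidly; switch to dense early
    if sp.issparse(A) and A.nnz > 0.25 * A.shape[0] * A.shape[1]:
        return as_dense(A)
    return A


def diffuse_objective(M, X, cfg: DenoiseConfig | None = None) -> ObjectiveTrace:
    """Trace of the self-supervised MSE along the diffusion.

    Iterates B_1 = M, B_n = s(B_{n-1}) s(M), resetting the diagonal at
    every step, and records MSE_n = mse(s(B_n) X, X).  Under
    ``run2best`` the trace ends one step after its first strict local
    minimum (plateaus continue); under ``full_scan`` it runs to
    ``max_iterations``.  If s(.) becomes undefined (a row's whole mass
    sits on the diagonal) the trace is truncated at the last valid
    step.
    """
    if cfg is None:
        cfg = DenoiseConfig()
    M_w = M.weights if isinstance(M, TransitionMatrix) else M
    Xv = _values(X)
    _check_stochastic(M_w, "diffuse_objective")

    S = deself_weights(M_w)  # s(M); raises if undefined at step 1
    A = S  # s(B_1)
    mses: list[float] = []
    truncated = False
    _check_invariant_operator(A, "diffuse_objective[n=1]")
    mses.append(mse(A @ Xv, Xv))
    n = 1
    while n < cfg.max_iterations:
        B = _maybe_densify(A @ S)
        try:
            A = deself_weights(B)
        except ValueError:
            truncated = True
            break
        _check_invariant_operator(A, f"diffuse_objective[n={n + 1}]")
        mses.append(mse(A @ Xv, Xv))
        n += 1
        if cfg.stop_rule == "run2best" and mses[-1] > mses[-2]:
            break
    arr = np.asarray(mses)
    n_star = int(np.argmin(arr)) + 1
    return ObjectiveTrace(arr, n_star, cfg, truncated)


def smoothing_operator(M, n_iterations: int):
    """s(B_n) for the requested depth, recomputed from M."""
    M_w = M.weights if isinstance(M, TransitionMatrix) else M
    _check_stochastic(M_w, "smoothing_operator")
    S = deself_weights(M_w)
    A = S
    for _ in range(1, n_iterations):
        A = deself_weights(_maybe_densify(A @ S))
    return A


def denoise(X, M, trace: ObjectiveTrace, n_override: int | None = None) -> DenoiseResult:
    """X* = s(B_{n*}) X at the trace's optimum (or a forced depth).

    ``n_override`` exposes deliberately non-optimal depths for
    oversmoothing diagnostics.
    """
    n_star = int(n_override) if n_override is not None else trace.optimal_iteration
    if n_star < 1:
        raise ValueError("iteration depth must be >= 1")
    A = smoothing_operator(M, n_star)
    Xv = _values(X)
    out = as_dense(A @ Xv)
    if isinstance(X, ExpressionMatrix):
        denoised = ExpressionMatrix(out, list(X.cell_ids), list(X.gene_ids), raw_counts=False)
    else:
        denoised = ExpressionMatrix.from_array(out)
    M_t = M if isinstance(M, TransitionMatrix) else TransitionMatrix(M, is_right_stochastic=True)
    return DenoiseResult(denoised, trace, M_t, n_star)


def no_reset_variant(M, X, n_max: int = 5) -> ObjectiveTrace:
    """Diagnostic trace WITHOUT the per-step diagonal reset.

    The diagonal is zeroed once (first application of s) and the
    operator is then powered: prediction at depth n uses s(M)^n, whose
    diagonal mass grows with n, so each data point increasingly
    predicts itself.  This demonstrates the overfitting failure mode;
    it is never used for model selection.
    """
    M_w = M.weights if isinstance(M, TransitionMatrix) else M
    Xv = _values(X)
    _check_stochastic(M_w, "no_reset_variant")
    S = deself_weights(M_w)
    P = S
    mses: list[float] = []
    for _ in range(n_max):
        mses.append(mse(P @ Xv, Xv))
        P = _maybe_densify(P @ S)
    arr = np.asarray(mses)
    return ObjectiveTrace(arr, int(np.argmin(arr)) + 1, None)


def _tie_key(rec: GridRecord):
    return (rec.mse, rec.n_components, rec.n_neighbors, 0 if rec.mode == "distances" else 1)


def grid_search(
    X,
    pcs_grid,
    neighbors_grid,
    modes=("distances", "connectivities"),
    alpha: float = 1.0,
    seed: int = 0,
    stop_rule: str = "run2best",
    max_iterations: int = 20,
    exact: bool | None = None,
    use_expression_base: bool = False,
) -> GridSearchResult:
    """Exhaustive search over (mode, neighbors, PCs).

    The embedding is computed once per PC count and the kNN graph once
    per (PCs, neighbors) pair; each configuration is scored by its
    objective-trace minimum.  Infeasible grid points (neighbors >=
    cells, PCs > min dims) are recorded as skipped, not silently
    dropped.
    """
    if isinstance(X, np.ndarray) or sp.issparse(X):
        X = ExpressionMatrix.from_array(X)
    pcs_grid = list(pcs_grid)
    neighbors_grid = list(neighbors_grid)
    modes = list(modes)
    if not pcs_grid or not neighbors_grid or not modes:
        raise ValueError("grids must be nonempty")

    records: list[GridRecord] = []
    skipped: list[dict] = []
    n_cells = X.n_cells
    for d in pcs_grid:
        if d > min(X.shape) and not use_expression_base:
            skipped.append({"pcs": d, "reason": f"pcs {d} > min(cells, genes)"})
            continue
        E = (
            pca_embed(X, d, seed=seed)
            if not use_expression_base
            else pca_embed(X, d, seed=seed, source="expression")
        )
        for u in neighbors_grid:
            if u >= n_cells:
                skipped.append(
                    {"pcs": d, "neighbors": u, "reason": f"neighbors {u} >= cells {n_cells}"}
                )
                continue
            G = build_knn(E, u, seed=seed, exact=exact)
            for mode in modes:
                M = transition_from_graph(G, mode=mode, alpha=alpha)
                cfg = DenoiseConfig(
                    n_components=d, n_neighbors=u, mode=mode, alpha=alpha,
                    max_iterations=max_iterations, stop_rule=stop_rule, seed=seed,
                )
                trace = diffuse_objective(M, X, cfg)
                rec = GridRecord(mode, u, d, trace.optimal_iteration, trace.optimal_mse, trace)
                logger.info(
                    "grid point mode=%s u=%d d=%d -> n*=%d MSE=%.6g trace=%s",
                    mode, u, d, rec.optimal_iteration, rec.mse,
                    np.array2string(trace.mse_per_iteration, precision=5),
                )
                records.append(rec)
    if not records:
        raise ValueError("grid search produced no feasible configurations")
    best = min(records, key=_tie_key)
    return GridSearchResult(records, best, skipped)
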