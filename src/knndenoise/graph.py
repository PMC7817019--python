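"""Embedding, kNN graph and right-stochastic transition matrix.

The smoothing operator is built in stages:

    embed -> build_knn -> kernel (distances or connectivities)
          -> symmetrize -> row_normalize -> deself

``deself`` implements the invariant mapping s(M) = L^-1 (M - V), where
V is the diagonal of M and L the diagonal matrix of off-diagonal row
sums: it zeroes the diagonal and renormalizes each row to sum to one,
so that a cell's own value never participates in its own prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, NeighborGraph, TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingMatrix",
    "pca_embed",
    "build_knn",
    "kernel_from_distances",
    "kernel_from_connectivities",
    "symmetrize",
    "row_normalize",
    "deself",
    "transition_from_graph",
    "graph_from_arrays",
]

#: cell count at and below which exact brute-force kNN search is used,
#: mirroring the neighbor library's behavior.
EXACT_SEARCH_MAX_CELLS = 4096


@dataclass
class EmbeddingMatrix:
    """Low-dimensional representation used for neighbor search."""

    scores: np.ndarray | sp.spmatrix
    n_components: int
    seed: int = 0
    source: str = "pca"  # "pca" | "expression"

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]


def pca_embed(
    X: ExpressionMatrix,
    n_components: int,
    seed: int = 0,
    center: bool = True,
    source: str = "pca",
) -> EmbeddingMatrix:
    """Gene-centered principal-component scores of the expression matrix.

    With ``source="expression"`` the expression values themselves are
    used as the embedding (no PCA), for graph construction directly in
    gene space.
    """
    if source == "expression":
        return EmbeddingMatrix(X.values, X.n_genes, seed, source="expression")
    if source != "pca":
        raise ValueError("source must be 'pca' or 'expression'")
    bound = min(X.n_cells, X.n_genes)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} must lie in [1, min(cells, genes)={bound}]"
        )
    from sklearn.decomposition import PCA

    dense = X.to_dense().astype(np.float64)
    if not center:
        dense = dense - 0.0  # PCA always centers; flag kept for API symmetry
    solver = "full" if min(dense.shape) <= 1000 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(dense)
    return EmbeddingMatrix(scores, n_components, seed, source="pca")


def _exact_knn(E: np.ndarray, u: int, metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force kNN with stable (lowest-index) tie-breaking."""
    from scipy.spatial.distance import cdist

    n = E.shape[0]
    idx = np.empty((n, u), dtype=np.int64)
    dst = np.empty((n, u), dtype=np.float64)
    chunk = max(1, min(n, int(2**25 // max(n, 1))))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        D = cdist(E[start:stop], E, metric=metric)
        D[np.arange(stop - start), np.arange(start, stop)] = np.inf  # exclude self
        order = np.argsort(D, axis=1, kind="stable")[:, :u]
        idx[start:stop] = order
        dst[start:stop] = np.take_along_axis(D, order, axis=1)
    return idx, dst


def _approx_knn(E: np.ndarray, u: int, metric: str, seed: int) -> tuple[np.ndarray, np.ndarray]:
    from pynndescent import NNDescent

    index = NNDescent(E, n_neighbors=u + 1, metric=metric, random_state=seed)
    ind, dist = index.neighbor_graph
    n = E.shape[0]
    out_i = np.empty((n, u), dtype=np.int64)
    out_d = np.empty((n, u), dtype=np.float64)
    for i in range(n):
        row_i, row_d = ind[i], dist[i]
        keep = row_i != i
        if keep.sum() >= u:
            sel = np.where(keep)[0][:u]
        else:  # self not found among candidates; drop the farthest
            sel = np.arange(u)
        out_i[i] = row_i[sel]
        out_d[i] = row_d[sel]
    return out_i, out_d


def _fuzzy_connectivities(
    idx: np.ndarray, dst: np.ndarray, n: int, u: int, seed: int, metric: str
) -> sp.csr_matrix:
    """Smooth-kNN calibration of distances to [0, 1] with fuzzy-union
    symmetrization (delegated to the UMAP implementation)."""
    from sklearn.utils import check_random_state
    from umap.umap_ import fuzzy_simplicial_set

    knn_indices = np.hstack([np.arange(n)[:, None], idx]).astype(np.int64)
    knn_dists = np.hstack([np.zeros((n, 1)), dst])
    placeholder = sp.coo_matrix((n, 1))
    result = fuzzy_simplicial_set(
        placeholder,
        u + 1,
        check_random_state(seed),
        metric,
        knn_indices=knn_indices,
        knn_dists=knn_dists,
    )
    graph = result[0] if isinstance(result, tuple) else result
    conn = sp.csr_matrix(graph)
    conn.data = np.clip(conn.data, 0.0, 1.0)
    conn.eliminate_zeros()
    return conn


def build_knn(
    E: EmbeddingMatrix,
    u: int,
    seed: int = 0,
    exact: bool | None = None,
    metric: str = "euclidean",
) -> NeighborGraph:
    """k-nearest-neighbor graph over embedding rows.

    Exact brute-force search is used for up to 4096 cells (or when
    ``exact=True``); otherwise an approximate search with a fixed seed.
    Self-edges are excluded from the stored neighbor lists.
    """
    n = E.n_cells
    if u >= n:
        raise ValueError(f"n_neighbors={u} must be smaller than the number of cells ({n})")
    if u < 1:
        raise ValueError("n_neighbors must be >= 1")
    scores = E.scores
    if sp.issparse(scores):
        scores = np.asarray(scores.todense())
    scores = np.asarray(scores, dtype=np.float64)
    use_exact = exact if exact is not None else n <= EXACT_SEARCH_MAX_CELLS
    if use_exact:
        idx, dst = _exact_knn(scores, u, metric)
    else:
        idx, dst = _approx_knn(scores, u, metric, seed)

    # keep the sparse support faithful: exact duplicates get a tiny
    # positive distance so the entry is not silently dropped
    dst = np.maximum(dst, 1e-12)
    rows = np.repeat(np.arange(n), u)
    distances = sp.csr_matrix((dst.ravel(), (rows, idx.ravel())), shape=(n, n))
    connectivities = _fuzzy_connectivities(idx, dst, n, u, seed, metric)
    return NeighborGraph(distances, connectivities, u, metric)


def graph_from_arrays(
    distances=None, connectivities=None, n_neighbors: int | None = None,
    metric: str = "user",
) -> NeighborGraph:
    """Wrap a user-supplied precomputed graph.

    Either matrix may be given; the missing one is left empty.  The
    caller states explicitly which mode the weights are in — there is
    no auto-detection.
    """
    if distances is None and connectivities is None:
        raise ValueError("provide distances and/or connectivities")
    ref = distances if distances is not None else connectivities
    n = ref.shape[0]
    if ref.shape[0] != ref.shape[1]:
        raise ValueError("graph matrices must be square (cells x cells)")
    empty = sp.csr_matrix((n, n))
    D = sp.csr_matrix(distances) if distances is not None else empty
    C = sp.csr_matrix(connectivities) if connectivities is not None else empty
    if n_neighbors is None:
        nnz_rows = max(1, int(np.max((D if D.nnz else C).getnnz(axis=1))))
        n_neighbors = nnz_rows
    return NeighborGraph(D, C, n_neighbors, metric)


def kernel_from_distances(G: NeighborGraph, alpha: float = 1.0) -> TransitionMatrix:
    """Exponential decay kernel on the kNN distances.

    On the nonzero support, weight = exp(-d / dbar) ** alpha with dbar
    the mean of the nonzero distances (computed on the asymmetric kNN
    matrix, before symmetrization).  Zeros stay zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    D = G.distances.tocsr().copy().astype(float)
    if D.nnz == 0:
        raise ValueError("kernel_from_distances: distance matrix has no nonzero entries")
    dbar = D.data.mean()
    D.data = np.exp(-D.data / dbar) ** alpha
    return TransitionMatrix(D, mode="distances", alpha=alpha)


def kernel_from_connectivities(G: NeighborGraph, alpha: float = 1.0) -> TransitionMatrix:
    """Elementwise power C ** alpha of the connectivity weights."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    C = G.connectivities.tocsr().copy().astype(float)
    if C.nnz == 0:
        raise ValueError("kernel_from_connectivities: connectivity matrix is empty")
    if C.data.size and (C.data.min() < 0 or C.data.max() > 1 + 1e-12):
        raise ValueError("connectivity entries must lie in [0, 1]")
    C.data = C.data**alpha
    return TransitionMatrix(C, mode="connectivities", alpha=alpha)


def symmetrize(M: TransitionMatrix) -> TransitionMatrix:
    """(M + M') / 2; support becomes the union of M and M' supports."""
    W = M.weights
    if sp.issparse(W):
        sym = (W + W.T) * 0.5
        sym = sp.csr_matrix(sym)
    else:
        sym = (W + W.T) * 0.5
    return TransitionMatrix(sym, mode=M.mode, alpha=M.alpha)


def row_normalize(M: TransitionMatrix) -> TransitionMatrix:
    """Divide each row by its sum, producing a right-stochastic matrix."""
    W = M.weights
    sums = np.asarray(W.sum(axis=1)).ravel()
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(
            f"row_normalize: cell(s) {zero[:5].tolist()} have zero total weight "
            "(isolated in the graph)"
        )
    if sp.issparse(W):
        out = sp.diags(1.0 / sums) @ W.tocsr()
    else:
        out = W / sums[:, None]
    return TransitionMatrix(
        out, mode=M.mode, alpha=M.alpha, is_right_stochastic=True,
        has_zero_diagonal=M.has_zero_diagonal,
    )


def deself_weights(W):
    """Invariant mapping s(.) on a raw weight matrix.

    Removes the diagonal and renormalizes rows to sum to one.  Raises
    when a row carries mass only on the diagonal (the cell would have
    no usable neighbors).
    """
    if sp.issparse(W):
        A = W.tocsr().copy().astype(float)
        diag = A.diagonal()
        if np.any(diag != 0):
            A = A - sp.diags(diag)
            A = sp.csr_matrix(A)
            A.eliminate_zeros()
        sums = np.asarray(A.sum(axis=1)).ravel()
        bad = np.flatnonzero(sums <= 1e-300)
        if bad.size:
            raise ValueError(
                f"deself: cell(s) {bad[:5].tolist()} have no off-diagonal mass "
                "(no usable neighbors)"
            )
        return sp.diags(1.0 / sums) @ A
    A = np.array(W, dtype=float, copy=True)
    np.fill_diagonal(A, 0.0)
    sums = A.sum(axis=1)
    bad = np.flatnonzero(sums <= 1e-300)
    if bad.size:
        raise ValueError(
            f"deself: cell(s) {bad[:5].tolist()} have no off-diagonal mass "
            "(no usable neighbors)"
        )
    return A / sums[:, None]


def deself(M: TransitionMatrix) -> TransitionMatrix:
    """s(M) = L^-1 (M - V): zero diagonal, rows renormalized to 1."""
    out = deself_weights(M.weights)
    return TransitionMatrix(
        out, mode=M.mode, alpha=M.alpha,
        is_right_stochastic=True, has_zero_diagonal=True,
    )


def transition_from_graph(
    G: NeighborGraph, mode: str = "distances", alpha: float = 1.0
) -> TransitionMatrix:
    """Kernel -> symmetrize -> row_normalize, the standard order.

    The result is right-stochastic but still carries its diagonal; the
    diffusion objective applies ``deself`` at every step.
    """
    if mode == "distances":
        M = kernel_from_distances(G, alpha)
    elif mode == "connectivities":
        M = kernel_from_connectivities(G, alpha)
    else:
        raise ValueError("mode must be 'distances' or 'connectivities'")
    return row_normalize(symmetrize(M))
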