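"""Shared fixtures: small synthetic datasets and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

import knndenoise as kd
from knndenoise.preprocess import freeman_tukey_array


def random_stochastic(rng, n, zero_diag=False, sparse_frac=0.0):
    """Random right-stochastic matrix with positive off-diagonal mass."""
    W = rng.random((n, n)) + 1e-3
    if sparse_frac:
        mask = rng.random((n, n)) < sparse_frac
        np.fill_diagonal(mask, False)
        W[mask] = 0.0
    if zero_diag:
        np.fill_diagonal(W, 0.0)
    return W / W.sum(axis=1, keepdims=True)


def naive_deself(M):
    """Literal invariant mapping: L^-1 (M - V) with dense diagonals."""
    M = np.asarray(M, dtype=float)
    V = np.diag(np.diag(M))
    off = M - V
    L = np.diag(off.sum(axis=1))
    return np.linalg.inv(L) @ off


def naive_diffusion_trace(M, X, n_max):
    """Recompute B_n = s(B_{n-1}) s(M) from scratch per step (dense)."""

    def B(n):
        if n == 1:
            return np.asarray(M, dtype=float)
        return naive_deself(B(n - 1)) @ naive_deself(M)

    out = []
    for n in range(1, n_max + 1):
        pred = naive_deself(B(n)) @ np.asarray(X, dtype=float)
        out.append(np.mean((pred - np.asarray(X, dtype=float)) ** 2))
    return np.asarray(out)


def loop_predict(P, X):
    """Entrywise double loop over the leave-self-out prediction."""
    P = np.asarray(P, dtype=float)
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    out = np.zeros((n, g))
    for k in range(n):
        for j in range(g):
            acc = 0.0
            for kk in range(n):
                if kk != k:
                    acc += P[k, kk] * X[kk, j]
            out[k, j] = acc
    return out


def loop_within_group_corr(X, groups):
    """All-pairs Pearson correlation oracle."""
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    vals = []
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                vals.append(np.corrcoef(X[idx[a]], X[idx[b]])[0, 1])
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def cluster_data():
    """300-cell / 3-group / 500-gene Poisson cluster fixture with the
    preprocessed matrix and aligned ground truth."""
    X, truth = kd.make_cluster_counts(300, 500, 3, seed=0)
    pp = kd.preprocess_counts(X)
    truth_pp = kd.subset_truth(truth, X, pp)
    spec = kd.FilterSpec()
    filtered = kd.filter_genes(kd.filter_cells(X, spec), spec.min_cells_per_gene)
    median_total = float(np.median(filtered.cell_totals()))
    return {
        "raw": X,
        "pp": pp,
        "truth": truth,
        "truth_pp": truth_pp,
        "median_total": median_total,
    }


@pytest.fixture(scope="session")
def cluster_grid(cluster_data):
    """Full-scan grid search over the acceptance grid (u x d x mode)."""
    return kd.grid_search(
        cluster_data["pp"],
        pcs_grid=[3, 10, 30],
        neighbors_grid=[5, 10, 25, 50, 100, 150],
        modes=["distances", "connectivities"],
        stop_rule="full_scan",
        max_iterations=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def mixture_data():
    X, truth = kd.make_mixture_counts(seed=0)
    pp = kd.preprocess_counts(X)
    truth_pp = kd.subset_truth(truth, X, pp)
    return {"raw": X, "pp": pp, "truth": truth, "truth_pp": truth_pp}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ftt():
    return freeman_tukey_array
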