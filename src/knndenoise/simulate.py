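"""Synthetic count generators with known ground truth.

Three designs cover the needs of testing and calibration:

* ``make_cluster_counts`` — discrete cell groups with i.i.d. log-normal
  mean profiles, log-normal depth factors and Poisson (optionally
  negative-binomial) sampling;
* ``make_mixture_counts`` — groups defined by mixture proportions over a
  small set of archetype profiles, emulating RNA-mixture benchmark
  designs where "cells" of a group share the same mRNA proportions from
  a few cell lines;
* ``make_lowrank_counts`` — Poisson counts around an exactly rank-r
  nonnegative mean matrix, for rank-recovery experiments.

Defaults emulate shallow UMI data: a grand-mean expected count of ~1
per gene per cell for the cluster design, and plate-scale depth (1000
counts/cell) for the mixture design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix

__all__ = [
    "GroundTruth",
    "make_cluster_counts",
    "make_mixture_counts",
    "make_lowrank_counts",
    "simplex_grid_proportions",
    "subset_truth",
]


@dataclass
class GroundTruth:
    """What the generator knows: per-group expected profiles and labels."""

    true_means: np.ndarray        # groups x genes expected counts (unit depth)
    group_labels: np.ndarray      # per-cell group index
    depth_factors: np.ndarray     # per-cell scaling
    generator_params: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return self.true_means.shape[0]

    def cell_means(self) -> np.ndarray:
        """Expected counts per cell (depth times group profile)."""
        return self.depth_factors[:, None] * self.true_means[self.group_labels]


def _sample_counts(rng, lam: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(lam)
    # gamma-Poisson: variance = lam + dispersion * lam^2
    shape = 1.0 / dispersion
    lam_nb = rng.gamma(shape, lam * dispersion)
    return rng.poisson(lam_nb)


def _wrap(counts: np.ndarray, prefix: str) -> ExpressionMatrix:
    return ExpressionMatrix.from_array(counts.astype(np.int64), raw_counts=True)


def make_cluster_counts(
    n_cells: int = 300,
    n_genes: int = 500,
    n_groups: int = 3,
    mean_scale: float = 1.0,
    seed: int = 0,
    profile_sigma: float = 1.0,
    depth_sigma: float = 0.3,
    dispersion: float | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Clustered counts: log-normal group profiles, Poisson sampling.

    ``mean_scale`` is the grand-mean expected count per (cell, gene) at
    unit depth.  Cells are assigned to groups round-robin, so groups
    have (near-)equal sizes.
    """
    if n_groups > n_cells:
        raise ValueError("n_groups must not exceed n_cells")
    if min(n_cells, n_genes, n_groups) < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0.0, profile_sigma, size=(n_groups, n_genes))
    true_means = raw * (mean_scale / raw.mean())
    labels = np.arange(n_cells) % n_groups
    depths = rng.lognormal(0.0, depth_sigma, size=n_cells)
    lam = depths[:, None] * true_means[labels]
    counts = _sample_counts(rng, lam, dispersion)
    truth = GroundTruth(
        true_means, labels, depths,
        {"design": "cluster", "n_cells": n_cells, "n_genes": n_genes,
         "n_groups": n_groups, "mean_scale": mean_scale,
         "noise": "poisson" if dispersion is None else f"nb(dispersion={dispersion})",
         "seed": seed},
    )
    return _wrap(counts, "cluster"), truth


def simplex_grid_proportions() -> np.ndarray:
    """Eight mixture groups on the 3-archetype simplex.

    Three pure archetypes, the three pairwise midpoints, the centroid,
    and one dominant-archetype blend — a small grid in the style of RNA
    mixture benchmarks.
    """
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.5, 0.5, 0.0],
            [0.5, 0.0, 0.5],
            [0.0, 0.5, 0.5],
            [1 / 3, 1 / 3, 1 / 3],
            [0.68, 0.16, 0.16],
        ]
    )


def make_mixture_counts(
    n_per_group: int = 30,
    proportions_grid: np.ndarray | None = None,
    archetypes: np.ndarray | int = 3,
    depth: float = 1000.0,
    seed: int = 0,
    n_genes: int = 500,
    depth_sigma: float = 0.3,
    dispersion: float | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Mixture-design counts: group mean = proportions @ archetypes.

    ``archetypes`` is either an (n_archetypes x n_genes) profile matrix
    or an integer count of log-normal archetypes to generate.  ``depth``
    is the expected total count per cell.  Every proportion vector must
    sum to 1.
    """
    rng = np.random.default_rng(seed)
    if proportions_grid is None:
        proportions_grid = simplex_grid_proportions()
    P = np.asarray(proportions_grid, dtype=float)
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("every proportion vector must sum to 1")
    if isinstance(archetypes, (int, np.integer)):
        arch = rng.lognormal(0.0, 1.0, size=(int(archetypes), n_genes))
    else:
        arch = np.asarray(archetypes, dtype=float)
    if P.shape[1] != arch.shape[0]:
        raise ValueError("proportion vectors and archetypes disagree on archetype count")
    # expected profiles at unit depth: each archetype normalized to sum 1
    arch = arch / arch.sum(axis=1, keepdims=True)
    true_means = P @ arch  # rows sum to 1
    n_groups = P.shape[0]
    n_cells = n_groups * n_per_group
    labels = np.repeat(np.arange(n_groups), n_per_group)
    depths = depth * rng.lognormal(0.0, depth_sigma, size=n_cells)
    lam = depths[:, None] * true_means[labels]
    counts = _sample_counts(rng, lam, dispersion)
    truth = GroundTruth(
        true_means, labels, depths,
        {"design": "mixture", "n_per_group": n_per_group, "depth": depth,
         "n_genes": arch.shape[1], "proportions": P.tolist(), "seed": seed,
         "noise": "poisson" if dispersion is None else f"nb(dispersion={dispersion})"},
    )
    return _wrap(counts, "mixture"), truth


def make_lowrank_counts(
    n_cells: int = 300,
    n_genes: int = 200,
    rank: int = 5,
    signal: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Poisson counts around an exactly rank-r nonnegative mean.

    ``signal`` is the grand-mean expected count per entry; larger values
    raise the signal-to-noise ratio of the latent factors.
    """
    if not 1 <= rank <= min(n_cells, n_genes):
        raise ValueError("rank must lie in [1, min(n_cells, n_genes)]")
    rng = np.random.default_rng(seed)
    W = rng.gamma(2.0, 1.0, size=(n_cells, rank))
    H = rng.lognormal(0.0, 1.0, size=(rank, n_genes))
    M = W @ H
    M *= signal / M.mean()
    counts = rng.poisson(M)
    # per-cell means: store cells as their own "groups"
    truth = GroundTruth(
        M, np.arange(n_cells), np.ones(n_cells),
        {"design": "lowrank", "n_cells": n_cells, "n_genes": n_genes,
         "rank": rank, "signal": signal, "seed": seed, "noise": "poisson"},
    )
    return _wrap(counts, "lowrank"), truth


def subset_truth(truth: GroundTruth, original: ExpressionMatrix,
                 filtered: ExpressionMatrix) -> GroundTruth:
    """Align ground truth with a filtered view of the generated matrix.

    Cell-level fields are subset to the retained cells and the true
    mean profiles to the retained genes, matched by label.
    """
    cmap = {c: i for i, c in enumerate(original.cell_ids)}
    gmap = {g: j for j, g in enumerate(original.gene_ids)}
    try:
        ci = np.array([cmap[c] for c in filtered.cell_ids])
        gj = np.array([gmap[g] for g in filtered.gene_ids])
    except KeyError as exc:
        raise ValueError(f"filtered matrix has label {exc} absent from the original")
    return GroundTruth(
        truth.true_means[:, gj],
        truth.group_labels[ci],
        truth.depth_factors[ci],
        dict(truth.generator_params),
    )
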