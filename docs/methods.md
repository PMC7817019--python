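# Methods

## Model and assumptions

The denoiser treats a cells × genes expression matrix **X** as noisy
observations of a smooth underlying state: cells that are close in a
low-dimensional embedding are assumed to share expression states, so a
weighted average over a cell's neighbors is a lower-variance estimate
of its true profile. The smoothing operator is a right-stochastic
transition matrix **M** derived from a kNN graph; smoothing depth is
controlled by diffusion, i.e. repeated application of the operator.

The estimator is tuned by a self-supervised leave-self-out objective.
The invariant mapping s(M) = L⁻¹(M − V) (V the diagonal of M, L the
diagonal matrix of off-diagonal row sums) removes each cell's own
weight and renormalizes, so the prediction s(Bₙ)X of entry (k, j) uses
gene j in every cell except k. Under the assumption that measurement
noise is independent across cells, the resulting MSE decomposes into
an irreducible noise floor plus estimator variance and bias, so its
minimizer over (PCs d, neighbors u, depth n) tracks the bias–variance
optimum without ground truth. Diffusion iterates Bₙ = s(Bₙ₋₁)·s(M)
with the diagonal reset at every step; each step is treated as an
independent Markov process precisely so the invariance (zero diagonal)
is preserved at all depths. The denoised output is X* = s(Bₙ\*)X.

Two failure modes frame the design:

* **Self-reference.** If the diagonal is zeroed only once and the
  operator is then powered (`no_reset_variant`), s(M)ⁿ accumulates
  diagonal mass and every cell partially predicts itself. The apparent
  MSE then drops below the honest trace from the second step onward.
  This trace is a diagnostic of the overfitting failure mode, never a
  selection criterion. In simulation the drop is sharpest at step 2 and
  the trace then fluctuates with the even/odd return probability of the
  walk, rather than decreasing monotonically.
* **Oversmoothing.** Excess depth compresses nearly all variance onto a
  few components. The variance-spectrum diagnostics quantify this: on
  the clustered synthetic design, one smoothing step at (u=10, d=10)
  needs ~37 components to explain 90% of the denoised variance, while a
  forced 8-step diffusion needs 2. The small-neighborhood configuration
  is used for this contrast deliberately: with u at or above the group
  size a single step already averages the whole group and depth adds
  little.

## Pipeline and parameters

Raw counts are preprocessed in a fixed order — cell threshold filters,
percentile clipping, gene support filter, median depth normalization,
Freeman–Tukey transform (FTT):

| parameter | default | meaning |
|---|---|---|
| `min_genes_per_cell`, `min_counts_per_cell` | 0 | explicit lower thresholds (counts) |
| `clip_percentile` | 0.005 | fraction clipped from each tail of the total-count distribution |
| `min_cells_per_gene` | 10 | gene kept only if expressed in strictly more cells |
| `n_components` (d) | 50 | PCA dimensionality for neighbor search |
| `n_neighbors` (u) | 50 | kNN neighborhood size |
| `mode` | distances | edge weights: exp(−D/d̄)^α on distances, or C^α on connectivities |
| `alpha` | 1.0 | decay exponent |
| `max_iterations` | 20 | diffusion-depth cap for the objective scan |
| `stop_rule` | run2best | stop one step past the first strict MSE increase |

Notes on the less obvious choices:

* The filtering order keeps gene support counts referring to retained
  cells. All preprocessing preserves sparse storage; the FTT maps zeros
  to zeros exactly.
* The distance kernel's scale d̄ is the mean of the nonzero entries of
  the *asymmetric* kNN distance matrix, computed before symmetrization;
  α is applied at the kernel stage, before symmetrization. The operator
  order is fixed: kernel → symmetrize ((M + Mᵀ)/2) → row-normalize →
  deself.
* α defaults to 1 (pure exponential kernel). Decay exponents
  interact with graph construction differently across published
  diffusion denoisers, so the least-assumption default is used and the
  exponent is exposed.
* Connectivities come from the UMAP fuzzy-simplicial-set calibration
  (smooth per-cell bandwidths with fuzzy-union symmetrization), with
  the self-edge included in the calibration arrays, so the bandwidth
  targets log₂(u + 1) effective neighbors — the neighbor library's own
  convention.
* Exact brute-force kNN (stable argsort, ties broken toward the lower
  cell index) is used up to 4096 cells or on request; above that, a
  seeded approximate search (pynndescent). Exact kNN distances of
  duplicate points are floored at 1e-12 so the sparse support is
  preserved (the kernel weight there is e⁰ = 1 either way).
* The objective is evaluated on the expression values themselves, not
  on PC scores; PCA serves only the neighbor search. The MSE is the
  mean over all matrix entries, making values comparable across matrix
  sizes (but not across normalizations).
* `run2best` continues through exact plateaus (MSE equal between
  steps) and stops only on a strict increase; the recorded trace ends
  one step past the minimum. If s(·) becomes undefined (a row's whole
  mass on the diagonal, e.g. the two-cell graph at depth 2) the trace
  truncates at the last valid depth.
* Grid-search ties are broken toward fewer PCs, then fewer neighbors,
  then the distances mode, for determinism.
* Bₙ is materialized (densifying once fill-in exceeds 25%) so its
  diagonal can be removed exactly; memory is O(cells²) in the worst
  case, acceptable because optimal depths in practice are 1–3.
* The kNN graph is built once from X and reused across all diffusion
  steps; a user-supplied graph (any metric, any construction) can be
  passed in and is used verbatim with an explicit distances/
  connectivities mode flag.

## Molecular cross-validation

Counts are split entrywise by binomial thinning, c_J ~ Binomial(c, p)
with p = 0.5, giving two independent halves with conserved sum. PCA is
fitted (column-centered SVD) on one half and the rank-r reconstruction
scored against the other half under squared loss; the held-out half is
rescaled by p/(1−p) to match expected depth. Loss is reported both in
count space and in the pipeline's transformed space (each half median-
normalized and FTT-transformed independently); selection uses the
transformed loss by default, count-space loss on request. Count-space
loss is the natural choice when the ground-truth rank is defined on
count means, as in the low-rank simulation; the U-shape of the curve
(underfitting left of the truth, noise-chasing right of it) is the
selection signal.

## Variance spectrum

Columns are standardized to mean 0 and population (divisor n) standard
deviation 1; zero-variance columns are dropped with a warning.
Singular values at or below max(S)·max(m, n)·ε, with ε the float32
machine epsilon regardless of storage precision, are treated as zero
(the cutoff is overridable). Relative variances η²ᵢ = sᵢ²/Σs² are
reported with cumulative sums, condition numbers sᵢ/s_min, and the
numerical rank; retained singular values are transpose-invariant.
Dense SVD is used up to 2000×2000 and a seeded randomized SVD above.

## Synthetic designs

* **Cluster**: group mean profiles drawn i.i.d. log-normal (σ = 1)
  per gene, scaled to a grand-mean expected count of 1 per gene per
  cell (shallow-UMI regime: ~500 counts per 500-gene cell); cells
  assigned round-robin; per-cell depth factors log-normal (σ = 0.3);
  Poisson sampling, with an optional gamma–Poisson dispersion knob.
* **Mixture**: eight groups defined by proportion vectors on a
  3-archetype simplex (pure corners, pairwise midpoints, centroid, one
  dominant blend); group mean = proportions × archetype profiles,
  expected depth 1000 counts/cell — emulating plate-based RNA-mixture
  benchmark designs where within-group differences are pure technical
  noise.
* **Low-rank**: Poisson counts around an exactly rank-5 nonnegative
  mean (gamma × log-normal factors), grand-mean 2 counts per entry.

What these designs do **not** emulate: batch effects, doublets,
zero-inflation beyond Poisson sparsity, gene–gene correlation within a
group, read-level artifacts, and continuous trajectories. Passing
tests on them therefore demonstrate the estimator's statistical
behavior under independent sampling noise with known structure — not
performance on any particular tissue. One visible consequence: with
few PCs the embedding separates groups poorly and the objective keeps
rewarding depth at small neighborhoods, so the optimal-depth-is-one
behavior appears once neighborhoods are large enough — the same
neighbor/depth trade-off seen on real data.

## Problem sizes

The test suite and the acceptance script run the full grid
(2 modes × 6 neighborhood sizes × 3 PC counts, 10-step full scans) on
the 300-cell cluster design, 10-seed rank-recovery on 300×200 counts,
and 10⁵-draw Monte-Carlo checks of the FTT — sizes chosen so every
property is measured in seconds while keeping all group-size effects
(u below, at, and above the within-group cell count) visible.

## Known limitations

* The objective's noise floor means MSE values are comparable only
  within one normalization of one dataset.
* With u ≥ cells/groups the graph mixes groups and the bias term grows
  quickly; the grid should always include neighborhoods below the
  expected group size.
* Approximate kNN (>4096 cells) is deterministic per seed but not
  identical to exact search; an `exact` override exists for
  reproducibility studies.
* The diffusion objective assumes noise independent across cells;
  strong ambient contamination or doublets violate this and bias the
  selected depth downward-optimistic.
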