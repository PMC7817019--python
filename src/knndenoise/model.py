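"""Model / Results interface over the functional core.

``DenoisingModel`` is constructed from a (normalized) expression
matrix plus graph hyperparameters; ``fit`` runs the self-supervised
diffusion objective and returns a ``DenoisingResults`` carrying the
denoised matrix, the MSE trace, the selected depth and diagnostics.
``fit_grid`` searches the (mode, neighbors, PCs) space and returns a
``GridSearchResults`` whose ``summary()`` is the familiar
one-row-per-configuration table.

Example
-------
>>> model = DenoisingModel(X, n_components=10, n_neighbors=50)
>>> res = model.fit()
>>> res.n_iterations_, res.mse_
>>> print(res.summary())
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import ExpressionMatrix, NeighborGraph, TransitionMatrix
from .diffusion import (
    DenoiseConfig,
    GridSearchResult,
    ObjectiveTrace,
    denoise,
    diffuse_objective,
    grid_search,
    no_reset_variant,
)
from .graph import build_knn, graph_from_arrays, pca_embed, transition_from_graph
from .variance import VarianceSpectrum, components_for_fraction, spectrum

__all__ = ["DenoisingModel", "DenoisingResults", "GridSearchResults"]


class DenoisingModel:
    """Self-supervised graph smoother for an expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix, ndarray, sparse matrix or DataFrame
        Normalized expression values, cells x genes.  Raw counts should
        be run through :func:`knndenoise.preprocess.preprocess_counts`
        first.
    n_components : int
        PCA dimensionality for the neighbor search (ignored when
        ``use_pca=False``, in which case neighbors are found directly in
        expression space).
    n_neighbors : int
        Neighborhood size u of the kNN graph.
    mode : {"distances", "connectivities"}
        Edge weighting: exponential-decay kernel on distances, or the
        fuzzy connectivities raised to ``alpha``.
    alpha : float
        Decay exponent of the kernel.
    graph : NeighborGraph, optional
        A precomputed neighbor graph; any externally derived graph can
        be supplied here, bypassing PCA and the internal kNN search.
    """

    def __init__(
        self,
        data,
        *,
        n_components: int = 50,
        n_neighbors: int = 50,
        mode: str = "distances",
        alpha: float = 1.0,
        use_pca: bool = True,
        metric: str = "euclidean",
        exact: bool | None = None,
        seed: int = 0,
        graph: NeighborGraph | None = None,
    ) -> None:
        if isinstance(data, ExpressionMatrix):
            self.data = data
        elif hasattr(data, "to_numpy") and hasattr(data, "columns"):
            self.data = ExpressionMatrix.from_dataframe(data)
        else:
            self.data = ExpressionMatrix.from_array(data)
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.mode = mode
        self.alpha = alpha
        self.use_pca = use_pca
        self.metric = metric
        self.exact = exact
        self.seed = seed
        self._graph = graph
        self._transition: TransitionMatrix | None = None

    # -- constructors --------------------------------------------------
    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "DenoisingModel":
        return cls(ExpressionMatrix.from_dataframe(df), **kwargs)

    @classmethod
    def from_graph(cls, data, graph, **kwargs) -> "DenoisingModel":
        """Build from a user-supplied graph (distances and/or
        connectivities); ``mode`` selects which weights are used."""
        if not isinstance(graph, NeighborGraph):
            raise TypeError("graph must be a NeighborGraph; see graph_from_arrays")
        return cls(data, graph=graph, **kwargs)

    # -- graph plumbing ------------------------------------------------
    def neighbor_graph(self) -> NeighborGraph:
        if self._graph is None:
            source = "pca" if self.use_pca else "expression"
            E = pca_embed(self.data, self.n_components, seed=self.seed, source=source)
            self._graph = build_knn(
                E, self.n_neighbors, seed=self.seed, exact=self.exact, metric=self.metric
            )
        return self._graph

    def transition_matrix(self) -> TransitionMatrix:
        if self._transition is None:
            self._transition = transition_from_graph(
                self.neighbor_graph(), mode=self.mode, alpha=self.alpha
            )
        return self._transition

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        stop_rule: str = "run2best",
        max_iterations: int = 20,
        n_iterations: int | None = None,
    ) -> "DenoisingResults":
        """Run the diffusion objective and denoise at its optimum.

        ``n_iterations`` forces a fixed depth (bypassing the stopping
        rule), e.g. for oversmoothing diagnostics.
        """
        cfg = DenoiseConfig(
            n_components=self.n_components,
            n_neighbors=self.n_neighbors,
            mode=self.mode,
            alpha=self.alpha,
            max_iterations=max_iterations,
            stop_rule=stop_rule,
            seed=self.seed,
        )
        M = self.transition_matrix()
        trace = diffuse_objective(M, self.data, cfg)
        result = denoise(self.data, M, trace, n_override=n_iterations)
        return DenoisingResults(self, result.denoised, trace, M, result.n_iterations)

    def fit_grid(
        self,
        n_components_grid,
        n_neighbors_grid,
        modes=("distances", "connectivities"),
        stop_rule: str = "run2best",
        max_iterations: int = 20,
    ) -> "GridSearchResults":
        """Hyperparameter search over (mode, neighbors, PCs)."""
        raw = grid_search(
            self.data,
            n_components_grid,
            n_neighbors_grid,
            modes=modes,
            alpha=self.alpha,
            seed=self.seed,
            stop_rule=stop_rule,
            max_iterations=max_iterations,
            exact=self.exact,
            use_expression_base=not self.use_pca,
        )
        return GridSearchResults(self, raw)

    def overfit_trace(self, n_max: int = 5) -> ObjectiveTrace:
        """No-diagonal-reset diagnostic trace (never for selection)."""
        return no_reset_variant(self.transition_matrix(), self.data, n_max)


class DenoisingResults:
    """Fitted smoother: denoised matrix, objective trace, diagnostics."""

    def __init__(self, model, denoised, trace, transition, n_iterations):
        self.model = model
        self.denoised: ExpressionMatrix = denoised
        self.trace: ObjectiveTrace = trace
        self.transition_: TransitionMatrix = transition
        self.n_iterations_: int = n_iterations

    @property
    def mse_path_(self) -> np.ndarray:
        return self.trace.mse_per_iteration

    @property
    def mse_(self) -> float:
        return float(self.trace.mse_per_iteration[self.n_iterations_ - 1])

    def variance_spectrum(self) -> VarianceSpectrum:
        return spectrum(self.denoised)

    def components_for_fraction(self, fraction: float) -> int:
        return components_for_fraction(self.variance_spectrum(), fraction)

    def summary(self) -> str:
        m = self.model
        spec = None
        lines = [
            "Self-supervised kNN denoising results",
            "=" * 46,
            f"cells                 {self.denoised.n_cells:>12d}",
            f"genes                 {self.denoised.n_genes:>12d}",
            f"mode                  {m.mode:>12s}",
            f"neighbors (u)         {m.n_neighbors:>12d}",
            f"PCs (d)               {m.n_components:>12d}" if m.use_pca
            else "embedding             expression",
            f"alpha                 {m.alpha:>12.3g}",
            f"iterations (n*)       {self.n_iterations_:>12d}",
            f"objective MSE         {self.mse_:>12.6g}",
            f"trace length          {len(self.trace):>12d}",
            "-" * 46,
            "MSE per iteration: "
            + np.array2string(self.mse_path_, precision=5, separator=", "),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DenoisingResults n*={self.n_iterations_} MSE={self.mse_:.5g} "
            f"mode={self.model.mode} u={self.model.n_neighbors}>"
        )


class GridSearchResults:
    """Outcome of ``DenoisingModel.fit_grid``."""

    def __init__(self, model: DenoisingModel, raw: GridSearchResult):
        self.model = model
        self.raw = raw

    @property
    def best_(self):
        return self.raw.best

    @property
    def frame(self):
        return self.raw.to_frame()

    def summary(self) -> str:
        b = self.raw.best
        head = (
            f"Grid search over {len(self.raw.records)} configurations "
            f"({len(self.raw.skipped)} skipped)\n"
            f"best: mode={b.mode} neighbors={b.n_neighbors} pcs={b.n_components} "
            f"iteration={b.optimal_iteration} MSE={b.mse:.6g}\n"
        )
        return head + self.frame.sort_values("MSE").to_string(index=False)

    def refit(self, n_iterations: int | None = None) -> DenoisingResults:
        """Fit a fresh model at the best configuration."""
        b = self.raw.best
        m = self.model
        best_model = DenoisingModel(
            m.data,
            n_components=b.n_components,
            n_neighbors=b.n_neighbors,
            mode=b.mode,
            alpha=m.alpha,
            use_pca=m.use_pca,
            metric=m.metric,
            exact=m.exact,
            seed=m.seed,
        )
        return best_model.fit(
            stop_rule="full_scan",
            max_iterations=max(b.optimal_iteration, 1),
            n_iterations=n_iterations or b.optimal_iteration,
        )
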