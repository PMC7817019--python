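import numpy as np
import pytest
import scipy.sparse as sp

import knndenoise as kd
from knndenoise.containers import TransitionMatrix

from conftest import (
    loop_predict,
    naive_deself,
    naive_diffusion_trace,
    random_stochastic,
)


def zero_diag_stochastic(rng, n):
    return TransitionMatrix(
        random_stochastic(rng, n, zero_diag=True),
        is_right_stochastic=True,
        has_zero_diagonal=True,
    )


class TestPredict:
    def test_three_cell_worked_example(self):
        P = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        X = np.array([[1.0, 0.0], [2.0, 2.0], [3.0, 4.0]])
        out = kd.predict(P, X)
        np.testing.assert_allclose(out, [[2.5, 3], [2, 2], [1.5, 1]])
        assert kd.mse(out, X) == pytest.approx(3.75)

    def test_constant_genes_are_fixed_points(self, rng):
        P = zero_diag_stochastic(rng, 12)
        X = np.tile(rng.normal(size=(1, 4)), (12, 1))
        np.testing.assert_allclose(kd.predict(P, X), X, atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            n, g = rng.integers(5, 30), rng.integers(2, 8)
            P = random_stochastic(rng, n, zero_diag=True)
            X = rng.normal(size=(n, g))
            np.testing.assert_allclose(
                kd.predict(P, X), loop_predict(P, X), atol=1e-10
            )

    def test_nonzero_diagonal_rejected(self, rng):
        P = random_stochastic(rng, 5)  # diagonal kept
        with pytest.raises(ValueError, match="diagonal"):
            kd.predict(P, rng.normal(size=(5, 3)))


class TestMSE:
    def test_zero_for_identical_and_homogeneous(self, rng):
        X = rng.normal(size=(6, 4))
        assert kd.mse(X, X) == 0.0
        Y = X + rng.normal(size=X.shape)
        base = kd.mse(Y, X)
        doubled = kd.mse(X + 2 * (Y - X), X)
        assert doubled == pytest.approx(4 * base)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kd.mse(rng.normal(size=(3, 2)), rng.normal(size=(2, 3)))

    def test_sparse_dense_agreement(self, rng):
        A = rng.poisson(1.0, (10, 8)).astype(float)
        B = rng.poisson(1.0, (10, 8)).astype(float)
        assert kd.mse(sp.csr_matrix(A), sp.csr_matrix(B)) == pytest.approx(kd.mse(A, B))


class TestDiffuseObjective:
    def test_two_cell_degenerate_case(self):
        # s(M) is the swap; the next step would be the identity, where
        # s is undefined -> trace truncates at length 1
        M = TransitionMatrix(np.full((2, 2), 0.5), is_right_stochastic=True)
        X = np.array([[0.0], [1.0]])
        trace = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=5, stop_rule="full_scan"))
        assert len(trace) == 1
        assert trace.optimal_iteration == 1
        assert trace.truncated
        assert trace.mse_per_iteration[0] == pytest.approx(1.0)

    def test_constant_data_yields_zero_mse_and_first_minimum(self, rng):
        M = TransitionMatrix(random_stochastic(rng, 8), is_right_stochastic=True)
        X = np.ones((8, 3))
        trace = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=4, stop_rule="run2best"))
        np.testing.assert_allclose(trace.mse_per_iteration, 0.0, atol=1e-20)
        # first-minimum rule: numerically zero error everywhere stops at 1
        assert trace.optimal_iteration == 1

    @pytest.mark.parametrize("n_cells", [10, 40])
    def test_matches_naive_recomputation_oracle(self, n_cells, rng):
        M = random_stochastic(rng, n_cells)
        X = rng.normal(size=(n_cells, 5))
        cfg = kd.DenoiseConfig(max_iterations=5, stop_rule="full_scan")
        trace = kd.diffuse_objective(
            TransitionMatrix(M, is_right_stochastic=True), X, cfg
        )
        oracle = naive_diffusion_trace(M, X, 5)
        np.testing.assert_allclose(trace.mse_per_iteration, oracle, atol=1e-9)

    def test_run2best_is_prefix_of_full_scan(self, cluster_data):
        pp = cluster_data["pp"]
        model = kd.DenoisingModel(pp, n_components=10, n_neighbors=10, seed=0)
        M = model.transition_matrix()
        full = kd.diffuse_objective(
            M, pp, kd.DenoiseConfig(max_iterations=8, stop_rule="full_scan")
        )
        early = kd.diffuse_objective(
            M, pp, kd.DenoiseConfig(max_iterations=8, stop_rule="run2best")
        )
        k = len(early)
        np.testing.assert_allclose(
            early.mse_per_iteration, full.mse_per_iteration[:k], rtol=1e-12
        )
        # run2best stops one step past the first local minimum
        mses = full.mse_per_iteration
        increases = np.where(np.diff(mses) > 0)[0]
        first_min = int(increases[0]) + 1 if increases.size else len(mses)
        assert early.optimal_iteration == first_min

    def test_requires_right_stochastic_input(self, rng):
        M = TransitionMatrix(rng.random((5, 5)))
        with pytest.raises(ValueError, match="right-stochastic"):
            kd.diffuse_objective(M, rng.normal(size=(5, 2)))


class TestDenoise:
    def test_depth_one_equals_single_prediction(self, rng):
        M = TransitionMatrix(random_stochastic(rng, 15), is_right_stochastic=True)
        X = rng.normal(size=(15, 4))
        trace = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=3, stop_rule="full_scan"))
        res = kd.denoise(X, M, trace, n_override=1)
        from knndenoise.graph import deself_weights

        direct = kd.predict(deself_weights(M.weights), X)  # bit-for-bit
        np.testing.assert_array_equal(res.denoised.to_dense(), direct)
        np.testing.assert_allclose(direct, kd.predict(naive_deself(M.weights), X),
                                   atol=1e-9)

    def test_reproducible_from_stored_components(self, rng):
        M = TransitionMatrix(random_stochastic(rng, 12), is_right_stochastic=True)
        X = rng.normal(size=(12, 3))
        trace = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=4, stop_rule="full_scan"))
        res = kd.denoise(X, M, trace)
        again = kd.denoise(X, res.transition, res.trace, n_override=res.n_iterations)
        np.testing.assert_array_equal(res.denoised.to_dense(), again.denoised.to_dense())

    def test_forced_depth_exposed_for_oversmoothing_diagnostics(self, rng):
        M = TransitionMatrix(random_stochastic(rng, 12), is_right_stochastic=True)
        X = rng.normal(size=(12, 3))
        trace = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=2, stop_rule="full_scan"))
        res = kd.denoise(X, M, trace, n_override=4)
        assert res.n_iterations == 4


class TestNoResetVariant:
    def test_first_step_identical_to_reset_trace(self, rng):
        M = TransitionMatrix(random_stochastic(rng, 20), is_right_stochastic=True)
        X = rng.normal(size=(20, 6))
        reset = kd.diffuse_objective(M, X, kd.DenoiseConfig(max_iterations=3, stop_rule="full_scan"))
        nores = kd.no_reset_variant(M, X, 3)
        assert nores.mse_per_iteration[0] == pytest.approx(reset.mse_per_iteration[0])

    def test_self_reference_lowers_apparent_error(self, cluster_data):
        """Without the diagonal reset the operator powers accumulate
        self-weight and each cell partially predicts itself, so the
        apparent MSE drops below the honest leave-self-out trace."""
        pp = cluster_data["pp"]
        model = kd.DenoisingModel(pp, n_components=10, n_neighbors=25, seed=0)
        M = model.transition_matrix()
        reset = kd.diffuse_objective(
            M, pp, kd.DenoiseConfig(max_iterations=5, stop_rule="full_scan")
        ).mse_per_iteration
        nores = kd.no_reset_variant(M, pp, 5).mse_per_iteration
        assert np.all(nores[1:] < reset[1:])


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self, rng):
        X = rng.poisson(5.0, (40, 30)).astype(float)
        res = kd.grid_search(X, [3], [5], modes=["distances"], seed=0,
                             stop_rule="full_scan", max_iterations=3)
        assert len(res.records) == 1
        assert res.best is res.records[0]

    def test_matches_exhaustive_reevaluation(self, rng):
        X = rng.poisson(5.0, (50, 30)).astype(float)
        res = kd.grid_search(X, [2, 5], [4, 8], modes=["distances", "connectivities"],
                             seed=0, stop_rule="full_scan", max_iterations=4)
        assert len(res.records) == 8
        # independent re-evaluation of each configuration
        for rec in res.records:
            E = kd.pca_embed(kd.ExpressionMatrix.from_array(X), rec.n_components, seed=0)
            G = kd.build_knn(E, rec.n_neighbors, seed=0)
            M = kd.transition_from_graph(G, rec.mode)
            oracle = naive_diffusion_trace(M.weights.toarray() if sp.issparse(M.weights) else M.weights,
                                           X, 4)
            np.testing.assert_allclose(rec.trace.mse_per_iteration, oracle, atol=1e-9)
        best_mse = min(r.mse for r in res.records)
        assert res.best.mse == best_mse

    def test_infeasible_points_recorded_not_silent(self, rng):
        X = rng.poisson(5.0, (20, 10)).astype(float)
        res = kd.grid_search(X, [3], [5, 25], modes=["distances"], seed=0,
                             stop_rule="full_scan", max_iterations=2)
        assert len(res.records) == 1
        assert any("neighbors 25" in s["reason"] for s in res.skipped)

    def test_deterministic_given_seed(self, rng):
        X = rng.poisson(5.0, (40, 20)).astype(float)
        a = kd.grid_search(X, [3], [5, 10], seed=7, stop_rule="full_scan", max_iterations=3)
        b = kd.grid_search(X, [3], [5, 10], seed=7, stop_rule="full_scan", max_iterations=3)
        assert a.to_frame().equals(b.to_frame())

    def test_tie_break_prefers_simpler_models(self):
        from knndenoise.diffusion import GridRecord, _tie_key

        t = kd.ObjectiveTrace(np.array([1.0]), 1)
        recs = [
            GridRecord("connectivities", 10, 5, 1, 0.5, t),
            GridRecord("distances", 10, 5, 1, 0.5, t),
            GridRecord("distances", 5, 5, 1, 0.5, t),
            GridRecord("distances", 5, 3, 1, 0.5, t),
        ]
        best = min(recs, key=_tie_key)
        assert (best.mode, best.n_neighbors, best.n_components) == ("distances", 5, 3)
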