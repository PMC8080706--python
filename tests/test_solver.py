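import numpy as np
import pytest

from ragnmf import (
    ConfigurationError,
    FactorizationState,
    NumericalError,
    RagnmfConfig,
    fit,
    objective,
    project_to_scaled_simplex,
)
from ragnmf.graph import build_graph
from ragnmf.solver import (
    feature_weight_costs,
    instance_weight_costs,
    load_state,
    save_state,
    update_basis,
    update_coefficients,
    update_feature_weights,
    update_instance_weights,
)


from _oracles import objective_oracle, simplex_projection_oracle


def _random_state(rng, m, p, k, uniform_weights=True):
    U = rng.random((m, k)) + 0.1
    Z = rng.random((p, k)) + 0.1
    W = np.ones(p) if uniform_weights else rng.random(p) + 0.1
    M = np.ones(m) if uniform_weights else rng.random(m) + 0.1
    return FactorizationState(U=U, Z=Z, W=W, M=M)


def _cfg(**kw):
    defaults = dict(k=2, lambda_graph=0.0, alpha=1.0, beta=1.0, C_w=1.0, C_m=1.0)
    defaults.update(kw)
    return RagnmfConfig(**defaults)


class TestObjective:
    def test_zero_at_exact_factorization_without_penalties(self, rng):
        U = rng.random((4, 2))
        Z = rng.random((5, 2))
        X = U @ Z.T
        state = FactorizationState(U=U, Z=Z, W=np.ones(5), M=np.ones(4))
        graph = build_graph((X > X.mean()).astype(float), sigma=1.0)
        cfg = _cfg(lambda_graph=0.0, alpha=0.0, beta=0.0)
        assert objective(X, state, graph, cfg) == pytest.approx(0.0, abs=1e-20)

    def test_zero_factors_leave_pure_data_term(self, rng):
        X = (rng.random((3, 4)) < 0.5).astype(float)
        state = FactorizationState(
            U=np.zeros((3, 2)), Z=np.zeros((4, 2)), W=np.full(4, 0.5), M=np.full(3, 2.0)
        )
        graph = build_graph(X, sigma=1.0)
        cfg = _cfg(alpha=0.3, beta=0.7)
        expected = (
            float(state.M @ X**2 @ state.W)
            + 0.3 * float(np.sum(state.W**2))
            + 0.7 * float(np.sum(state.M**2))
        )
        assert objective(X, state, graph, cfg) == pytest.approx(expected, rel=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        X = (rng.random((4, 5)) < 0.5).astype(float)
        graph = build_graph(X, sigma=0.9)
        state = _random_state(rng, 4, 5, 2, uniform_weights=False)
        cfg = _cfg(lambda_graph=0.7, alpha=0.2, beta=0.4)
        assert objective(X, state, graph, cfg) == pytest.approx(
            objective_oracle(X, state, graph, cfg), rel=1e-10
        )

    def test_nan_state_raises(self, rng):
        X = np.ones((3, 3))
        state = _random_state(rng, 3, 3, 2)
        state.U[0, 0] = np.nan
        graph = build_graph(X, sigma=1.0)
        with pytest.raises(NumericalError):
            objective(X, state, graph, _cfg())

    def test_shape_mismatch_rejected(self, rng):
        X = np.ones((3, 4))
        state = _random_state(rng, 3, 5, 2)
        graph = build_graph(X, sigma=1.0)
        with pytest.raises(ConfigurationError):
            objective(X, state, graph, _cfg())


class TestMultiplicativeUpdates:
    def test_basis_fixed_point_at_exact_factorization(self, rng):
        U = rng.random((4, 2)) + 0.5
        Z = rng.random((6, 2)) + 0.5
        X = U @ Z.T
        state = FactorizationState(U=U, Z=Z, W=rng.random(6) + 0.1, M=rng.random(4) + 0.1)
        np.testing.assert_allclose(update_basis(X, state, _cfg()), U, rtol=1e-10)

    def test_uniform_weights_reduce_to_classical_nmf_updates(self, rng):
        X = (rng.random((5, 7)) < 0.5).astype(float)
        state = _random_state(rng, 5, 7, 3)
        cfg = _cfg(k=3, lambda_graph=0.0)
        # classical multiplicative updates as independent oracle
        U_classic = state.U * (X @ state.Z) / np.maximum(state.U @ state.Z.T @ state.Z, 1e-12)
        np.testing.assert_allclose(update_basis(X, state, cfg), U_classic, rtol=1e-12)
        graph = build_graph(X, sigma=1.0)
        Z_classic = state.Z * (X.T @ state.U) / np.maximum(
            state.Z @ state.U.T @ state.U, 1e-12
        )
        np.testing.assert_allclose(
            update_coefficients(X, state, graph, cfg), Z_classic, rtol=1e-12
        )

    def test_coefficients_fixed_point_without_graph(self, rng):
        U = rng.random((4, 2)) + 0.5
        Z = rng.random((6, 2)) + 0.5
        X = U @ Z.T
        state = FactorizationState(U=U, Z=Z, W=rng.random(6) + 0.1, M=rng.random(4) + 0.1)
        graph = build_graph((X > 0.5).astype(float), sigma=1.0)
        np.testing.assert_allclose(
            update_coefficients(X, state, graph, _cfg(lambda_graph=0.0)), Z, rtol=1e-10
        )

    def test_single_steps_never_increase_their_objectives(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            m, p, k = 4, 6, 2
            X = (rng.random((m, p)) < 0.5).astype(float)
            state = _random_state(rng, m, p, k, uniform_weights=False)
            graph = build_graph(X, sigma=1.0)
            cfg = _cfg(lambda_graph=0.5)

            def weighted_loss(st):
                R = X - st.U @ st.Z.T
                return float(st.M @ R**2 @ st.W)

            def loss_plus_graph(st):
                return weighted_loss(st) + cfg.lambda_graph * float(
                    np.sum(st.Z * (graph.laplacian @ st.Z))
                )

            before = weighted_loss(state)
            state.U = update_basis(X, state, cfg)
            assert weighted_loss(state) <= before + 1e-9 * max(1.0, before)

            before = loss_plus_graph(state)
            state.Z = update_coefficients(X, state, graph, cfg)
            assert loss_plus_graph(state) <= before + 1e-9 * max(1.0, before)

    def test_updates_preserve_nonnegativity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = (rng.random((5, 6)) < 0.5).astype(float)
            state = _random_state(rng, 5, 6, 2, uniform_weights=False)
            graph = build_graph(X, sigma=1.0)
            cfg = _cfg(lambda_graph=0.3)
            assert (update_basis(X, state, cfg) >= 0).all()
            assert (update_coefficients(X, state, graph, cfg) >= 0).all()


class TestWeightCosts:
    def test_zero_residual_gives_zero_costs(self, rng):
        U = rng.random((3, 2))
        Z = rng.random((4, 2))
        X = U @ Z.T
        state = FactorizationState(U=U, Z=Z, W=np.ones(4), M=rng.random(3))
        np.testing.assert_allclose(instance_weight_costs(X, state), 0.0, atol=1e-20)

    def test_matches_double_loop_oracle(self, rng):
        X = (rng.random((4, 5)) < 0.5).astype(float)
        state = _random_state(rng, 4, 5, 2, uniform_weights=False)
        R = X - state.U @ state.Z.T
        expected = np.array(
            [sum(state.M[s] * R[s, g] ** 2 for s in range(4)) for g in range(5)]
        )
        np.testing.assert_allclose(instance_weight_costs(X, state), expected, atol=1e-12)
        expected_feat = np.array(
            [sum(state.W[g] * R[s, g] ** 2 for g in range(5)) for s in range(4)]
        )
        np.testing.assert_allclose(feature_weight_costs(X, state), expected_feat, atol=1e-12)


class TestSimplexProjection:
    def test_feasible_point_is_unchanged(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(project_to_scaled_simplex(v, 1.0), v, atol=1e-12)

    def test_worked_example(self):
        np.testing.assert_allclose(
            project_to_scaled_simplex(np.array([2.0, 0.0]), 1.0), [1.0, 0.0], atol=1e-12
        )

    def test_matches_active_set_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = rng.integers(2, 6)
            v = rng.standard_normal(n) * rng.choice([0.1, 1.0, 10.0])
            budget = float(rng.random() * 3 + 0.1)
            got = project_to_scaled_simplex(v, budget)
            expected = simplex_projection_oracle(v, budget)
            np.testing.assert_allclose(got, expected, atol=1e-8)
            assert got.sum() == pytest.approx(budget, abs=1e-8)
            assert (got >= 0).all()


class TestWeightUpdates:
    def test_constant_costs_give_uniform_weights(self):
        cfg = _cfg(alpha=0.5, C_w=4.0)
        W = update_instance_weights(np.full(8, 3.3), cfg)
        np.testing.assert_allclose(W, 0.5, atol=1e-12)

    def test_outlier_cost_driven_to_zero(self):
        costs = np.array([1.0, 1.0, 1.0, 50.0])
        W = update_instance_weights(costs, _cfg(alpha=0.1, C_w=4.0))
        assert W[3] == 0.0
        assert W[:3].sum() == pytest.approx(4.0)

    def test_matches_numeric_simplex_minimizer(self, rng):
        from scipy.optimize import minimize

        costs = rng.random(6) * 5
        alpha, budget = 0.8, 2.0
        cfg = _cfg(alpha=alpha, C_w=budget)
        W = update_instance_weights(costs, cfg)

        def f(w):
            return float(costs @ w + alpha * w @ w)

        res = minimize(
            f,
            np.full(6, budget / 6),
            method="SLSQP",
            bounds=[(0, None)] * 6,
            constraints={"type": "eq", "fun": lambda w: w.sum() - budget},
        )
        assert f(W) <= res.fun + 1e-6

    def test_feature_update_mirrors_instance_update_under_transpose(self, rng):
        X = (rng.random((5, 6)) < 0.5).astype(float)
        state = _random_state(rng, 5, 6, 2, uniform_weights=False)
        cfg = _cfg(alpha=0.7, beta=0.7, C_w=3.0, C_m=3.0)
        M_direct = update_feature_weights(X, state, cfg)
        # transpose: swap roles of samples and genes
        state_t = FactorizationState(U=state.Z, Z=state.U, W=state.M, M=state.W)
        M_via_instance = update_instance_weights(instance_weight_costs(X.T, state_t), cfg)
        np.testing.assert_allclose(M_direct, M_via_instance, atol=1e-12)

    def test_zero_residual_gives_uniform_feature_weights(self, rng):
        U = rng.random((4, 2))
        Z = rng.random((5, 2))
        X = U @ Z.T
        state = FactorizationState(U=U, Z=Z, W=np.ones(5), M=np.ones(4))
        M = update_feature_weights(X, state, _cfg(beta=1.0, C_m=4.0))
        np.testing.assert_allclose(M, 1.0, atol=1e-10)


class TestFit:
    def test_infinite_tolerance_runs_exactly_one_iteration(self, rng):
        X = (rng.random((8, 10)) < 0.4).astype(float)
        X[0, :] = 1  # avoid empty rows
        state = fit(X, RagnmfConfig(k=2, tol=np.inf, seed=0, n_init=1))
        assert len(state.objective_history) == 1

    def test_same_seed_gives_bitwise_identical_history(self, rng):
        X = (rng.random((10, 14)) < 0.4).astype(float)
        cfg = RagnmfConfig(k=2, seed=42, max_iter=30)
        h1 = fit(X, cfg).objective_history
        h2 = fit(X, cfg).objective_history
        assert h1 == h2

    def test_recovers_planted_rank_two_structure(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            A = (rng.random((12, 2)) < 0.5).astype(int)
            A[:, 0] |= np.arange(12) < 4  # ensure both factors used
            B = (rng.random((16, 2)) < 0.5).astype(int)
            B[:, 1] |= np.arange(16) < 4
            X = np.minimum(A @ B.T, 1).astype(float)
            state = fit(X, RagnmfConfig(k=2, seed=seed, mode="gnmf", lambda_graph=0.0))
            rel_err = np.linalg.norm(X - state.U @ state.Z.T) / np.linalg.norm(X)
            errs.append(rel_err)
        assert np.mean(errs) < 0.15

    def test_k_too_large_rejected(self, rng):
        X = (rng.random((5, 6)) < 0.5).astype(float)
        with pytest.raises(ConfigurationError, match="k="):
            fit(X, RagnmfConfig(k=5))

    def test_history_non_increasing_and_invariants_hold(self, rng):
        X = (rng.random((12, 15)) < 0.35).astype(float)
        X[:, X.sum(axis=0) == 0] = rng.integers(0, 2, (12, (X.sum(axis=0) == 0).sum()))
        cfg = RagnmfConfig(k=3, seed=5, max_iter=80, weight_warmup=10)
        state = fit(X, cfg)
        h = np.array(state.objective_history)
        assert ((h[1:] - h[:-1]) / h[:-1]).max() <= 1e-6
        assert (state.U >= 0).all() and (state.Z >= 0).all()
        assert (state.W >= 0).all() and (state.M >= 0).all()
        resolved = cfg.resolve(*X.shape)
        assert state.W.sum() == pytest.approx(resolved.C_w, abs=1e-8)
        assert state.M.sum() == pytest.approx(resolved.C_m, abs=1e-8)

    def test_gnmf_mode_objective_reduces_to_unweighted_form(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            X = (rng.random((6, 8)) < 0.5).astype(float)
            state = _random_state(rng, 6, 8, 2, uniform_weights=True)
            graph = build_graph(X, sigma=1.0)
            cfg = RagnmfConfig(
                k=2, mode="gnmf", lambda_graph=0.4, alpha=0.3, beta=0.5, C_w=8.0, C_m=6.0
            )
            # with default budgets C_w=p, C_m=m uniform weights equal 1
            full = objective(X, state, graph, cfg)
            frozen = 0.3 * 8.0 + 0.5 * 6.0  # alpha*p + beta*m at uniform weights
            plain = float(np.sum((X - state.U @ state.Z.T) ** 2)) + 0.4 * float(
                np.sum(state.Z * (graph.laplacian @ state.Z))
            )
            assert full - frozen == pytest.approx(plain, rel=1e-10)

    def test_driversub_mode_sparsifies_coefficients(self, rng):
        X = (rng.random((10, 16)) < 0.4).astype(float)
        st_sparse = fit(
            X, RagnmfConfig(k=2, seed=3, mode="driversub", lambda_z=0.3, max_iter=60)
        )
        st_plain = fit(X, RagnmfConfig(k=2, seed=3, mode="gnmf", max_iter=60))
        assert (st_sparse.Z == 0).sum() > (st_plain.Z == 0).sum()

    def test_balanced_basis_columns_have_unit_norm(self, rng):
        X = (rng.random((10, 14)) < 0.4).astype(float)
        state = fit(X, RagnmfConfig(k=2, seed=0, max_iter=40))
        np.testing.assert_allclose(np.linalg.norm(state.U, axis=0), 1.0, rtol=1e-8)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        X = (rng.random((6, 9)) < 0.5).astype(float)
        state = fit(X, RagnmfConfig(k=2, seed=1, max_iter=20))
        path = tmp_path / "model.npz"
        save_state(state, path, genes=[f"g{i}" for i in range(9)], samples=[f"s{i}" for i in range(6)])
        back, genes, samples = load_state(path)
        np.testing.assert_array_equal(back.U, state.U)
        np.testing.assert_array_equal(back.Z, state.Z)
        assert back.objective_history == state.objective_history
        assert genes == [f"g{i}" for i in range(9)]
        assert back.config.k == 2


class TestRobustWeighting:
    def test_noisy_genes_get_lower_weight_than_clean(self):
        """Dense unstructured gene columns should be down-weighted (small cohorts)."""
        from ragnmf import CohortSpec, simulate_cohort

        wins = 0
        for seed in range(5):
            X, truth = simulate_cohort(
                CohortSpec(n_samples=60, n_genes=150, k_subgroups=3, drivers_per_subgroup=5, seed=seed)
            )
            state = fit(X, RagnmfConfig(k=3, seed=seed, n_init=2, max_iter=250))
            noisy = set(truth.noisy_genes)
            w_noisy = np.mean([w for g, w in zip(X.genes, state.W) if g in noisy])
            w_clean = np.mean([w for g, w in zip(X.genes, state.W) if g not in noisy])
            wins += w_noisy < w_clean
        assert wins >= 4


class TestSimplexProjectionProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=8),
        st.floats(min_value=0.01, max_value=20),
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_projection_is_feasible_and_idempotent(self, v, budget):
        w = project_to_scaled_simplex(np.array(v), budget)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(budget, rel=1e-9, abs=1e-9)
        np.testing.assert_allclose(project_to_scaled_simplex(w, budget), w, atol=1e-9)
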