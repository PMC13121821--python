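"""Schedules, per-item updates, and the streaming Newton engine."""

import numpy as np
import pytest
from conftest import random_instance

from irtstream.model import (
    ItemParamSet,
    ItemParamVector,
    ResponseVector,
    build_quadrature_grid,
    examinee_objective,
    posterior_node_weights,
)
from irtstream.online import (
    EstimatorConfig,
    OnlineEstimator,
    OnlineItemState,
    accumulate_hessian,
    averaging_weight,
    eap_ability,
    item_curvature,
    item_gradient,
    standard_errors,
    step_size,
    truncation_floor,
    update_item,
)

SIG1 = 0.7310585786300049


def cfg(**kw):
    return EstimatorConfig(**kw)


class TestSchedules:
    def test_step_size_values(self):
        assert step_size(1, cfg(gamma=0.7, c_nu=1, n0=0)) == pytest.approx(1.0)
        assert step_size(100, cfg(gamma=0.65, c_nu=1, n0=0)) == pytest.approx(
            100 ** (-0.65), abs=1e-6
        )  # = 0.050119

    def test_step_delay_damps_early_steps(self):
        assert step_size(1, cfg(n0=20)) < step_size(1, cfg(n0=0))
        ns = np.arange(1, 50)
        vals = [step_size(n, cfg()) for n in ns]
        assert np.all(np.diff(vals) < 0)

    def test_truncation_floor_values(self):
        c = cfg(c_lambda=0.2, alpha_lambda=0.49)
        assert truncation_floor(1, c) == pytest.approx(0.2 * 2 ** (-0.49), abs=1e-5)
        # 0.14240 by direct evaluation
        assert truncation_floor(1, c) == pytest.approx(0.14240, abs=1e-5)

    def test_truncation_floor_bounded_and_decaying(self):
        c = cfg(c_lambda=0.25, alpha_lambda=0.49)
        floors = [truncation_floor(n, c) for n in (1, 10, 1000, 10**6)]
        assert all(f <= 0.25 for f in floors)
        assert np.all(np.diff(floors) < 0)
        assert truncation_floor(10**9, c) < 1e-3

    def test_invalid_truncation_scale_rejected(self):
        with pytest.raises(ValueError, match="c_lambda"):
            cfg(c_lambda=0.3)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            cfg(gamma=0.5)


class TestAveragingWeight:
    def test_none_mode_is_identity(self):
        c = cfg(avg_mode="none")
        assert all(averaging_weight(n, c) == 1.0 for n in (1, 2, 50))

    def test_uniform_mode_gives_arithmetic_mean(self, rng):
        c = cfg(avg_mode="uniform")
        betas = rng.standard_normal(10)
        avg = 0.0
        for n, b in enumerate(betas, start=1):
            tau = averaging_weight(n, c)
            avg = (1 - tau) * avg + tau * b
        assert avg == pytest.approx(betas.mean(), rel=1e-12)

    def test_log_weight_zero_equals_uniform(self):
        cu = cfg(avg_mode="uniform")
        cl = cfg(avg_mode="log", avg_w=0.0)
        for n in (1, 2, 7, 100):
            assert averaging_weight(n, cl) == pytest.approx(
                averaging_weight(n, cu), rel=1e-12
            )

    def test_log_weighted_normalization(self):
        # tau_n = omega_n / cumsum(omega); weights reconstruct to a proper
        # weighted mean of the iterates
        c = cfg(avg_mode="log", avg_w=2.0)
        n = 25
        taus = [averaging_weight(i, c) for i in range(1, n + 1)]
        w = np.ones(n)
        for i in range(n):
            w[:i] *= 1 - taus[i]
            w[i] = taus[i]
        omega = np.log1p(np.arange(1, n + 1)) ** 2
        np.testing.assert_allclose(w, omega / omega.sum(), rtol=1e-10)


class TestItemGradient:
    def test_hand_example(self, two_node_grid, unit_item, unit_item_set, correct_response):
        post = posterior_node_weights(correct_response, unit_item_set, two_node_grid)
        g = item_gradient(1.0, post, unit_item, two_node_grid)
        np.testing.assert_allclose(g, [0.0, -2 * SIG1 * (1 - SIG1)], atol=1e-9)

    def test_sign_symmetry(self, two_node_grid, unit_item, unit_item_set):
        post = posterior_node_weights(ResponseVector([0]), unit_item_set, two_node_grid)
        g = item_gradient(0.0, post, unit_item, two_node_grid)
        np.testing.assert_allclose(g, [0.0, +2 * SIG1 * (1 - SIG1)], atol=1e-9)

    def test_zero_residual(self, unit_item):
        # posterior concentrated at the origin where P = y = 0.5 is
        # impossible for binary y; use a degenerate grid at a point where
        # P matches y exactly via an anchored flat item
        grid = build_quadrature_grid(1, 1)
        flat = ItemParamVector(np.array([0.0]), 0.0)
        g = item_gradient(0.5, np.array([1.0]), flat, grid)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_matches_finite_differences_of_objective(self, rng):
        """The per-item gradient is the exact score of the marginal objective."""
        worst = 0.0
        for _ in range(100):
            params, y, grid = random_instance(rng)
            beta = params.beta_matrix()
            post = posterior_node_weights(y, params, grid)
            j = int(rng.integers(0, params.J))
            g = item_gradient(y.values[j], post, params.items[j], grid)
            h = 1e-6
            fd = np.zeros(beta.shape[1])
            for p in range(beta.shape[1]):
                bp, bm = beta.copy(), beta.copy()
                bp[j, p] += h
                bm[j, p] -= h
                fd[p] = (
                    examinee_objective(y, ItemParamSet.from_arrays(bp), grid)
                    - examinee_objective(y, ItemParamSet.from_arrays(bm), grid)
                ) / (2 * h)
            worst = max(worst, np.max(np.abs(g - fd) / (np.abs(fd) + 1e-8)))
        assert worst <= 1e-6


class TestItemCurvature:
    def test_hand_example(self, two_node_grid, unit_item, unit_item_set, correct_response):
        post = posterior_node_weights(correct_response, unit_item_set, two_node_grid)
        Phi = item_curvature(post, unit_item, two_node_grid, floor=0.0)
        pq = SIG1 * (1 - SIG1)  # P(1-P) identical at both nodes
        off = pq * (SIG1 - (1 - SIG1))
        np.testing.assert_allclose(Phi, [[pq, off], [off, pq]], atol=1e-9)

    def test_floor_dominates_for_extreme_item(self, two_node_grid):
        extreme = ItemParamVector(np.array([30.0]), 0.0)
        post = np.array([0.3, 0.7])
        Phi = item_curvature(post, extreme, two_node_grid, floor=0.01)
        X = two_node_grid.augmented
        expected = 0.01 * (X.T * post) @ X
        np.testing.assert_allclose(Phi, expected, rtol=1e-6)

    def test_symmetric_psd(self, rng):
        for _ in range(25):
            params, y, grid = random_instance(rng)
            post = posterior_node_weights(y, params, grid)
            Phi = item_curvature(post, params.items[0], grid, floor=0.0)
            np.testing.assert_allclose(Phi, Phi.T, atol=1e-12)
            v = rng.standard_normal(Phi.shape[0])
            assert v @ Phi @ v >= -1e-12


class TestAccumulateHessian:
    def test_matrix_sum(self, two_node_grid, unit_item, unit_item_set, correct_response):
        post = posterior_node_weights(correct_response, unit_item_set, two_node_grid)
        Phi = item_curvature(post, unit_item, two_node_grid, floor=0.0)
        st = OnlineItemState(unit_item, unit_item, np.eye(2))
        accumulate_hessian(st, Phi)
        np.testing.assert_allclose(st.S, np.eye(2) + Phi)

    def test_zero_leaves_unchanged(self, unit_item):
        st = OnlineItemState(unit_item, unit_item, np.eye(2))
        accumulate_hessian(st, np.zeros((2, 2)))
        np.testing.assert_allclose(st.S, np.eye(2))

    def test_cesaro_limit(self, unit_item):
        Phi = np.array([[0.3, 0.1], [0.1, 0.3]])
        st = OnlineItemState(unit_item, unit_item, np.eye(2))
        n = 5000
        for _ in range(n):
            accumulate_hessian(st, Phi)
        np.testing.assert_allclose(st.S / (n + 1), Phi, atol=2e-4)


class TestUpdateItem:
    def test_fully_anchored_item_is_fixed(self, two_node_grid):
        anchored = ItemParamVector(
            np.array([1.0]), 0.0, np.zeros(2, dtype=bool)
        )
        st = OnlineItemState(anchored, anchored, np.eye(2))
        post = np.array([0.3, 0.7])
        st = update_item(st, 1.0, two_node_grid, cfg(), post, post)
        np.testing.assert_allclose(st.beta_current.beta, [1.0, 0.0])
        np.testing.assert_allclose(st.beta_avg.beta, [1.0, 0.0])
        assert st.n == 1

    def test_identity_hessian_hand_step(self, two_node_grid, unit_item, unit_item_set, correct_response):
        post = posterior_node_weights(correct_response, unit_item_set, two_node_grid)
        st = OnlineItemState(
            ItemParamVector(np.array([1.0]), 0.0),
            ItemParamVector(np.array([1.0]), 0.0),
            np.eye(2),
        )
        c = EstimatorConfig(gamma=1.0, c_nu=1.0, n0=0.0, avg_mode="none")
        st = update_item(st, 1.0, two_node_grid, c, post, post)
        np.testing.assert_allclose(
            st.beta_current.beta, [1.0, 2 * SIG1 * (1 - SIG1)], atol=1e-7
        )
        np.testing.assert_allclose(st.beta_avg.beta, st.beta_current.beta)

    def test_agrees_with_vectorized_engine(self, rng):
        """Per-item updates replayed one-by-one match the joint engine."""
        params, _, grid = random_instance(rng, J=3, Q=1, K=5)
        config = EstimatorConfig(K=5, Q=1)
        engine = OnlineEstimator(params, config, grid)
        states = [
            OnlineItemState(
                ItemParamVector(it.loadings.copy(), it.intercept, it.free_mask.copy()),
                ItemParamVector(it.loadings.copy(), it.intercept, it.free_mask.copy()),
                engine.S[j].copy(),
            )
            for j, it in enumerate(params.items)
        ]
        for _ in range(30):
            y = ResponseVector(rng.integers(0, 2, 3))
            cur = ItemParamSet.from_arrays(
                np.stack([s.beta_current.beta for s in states])
            )
            avg = ItemParamSet.from_arrays(
                np.stack([s.beta_avg.beta for s in states])
            )
            post_g = posterior_node_weights(y, cur, grid)
            post_h = posterior_node_weights(y, avg, grid)
            for j, s in enumerate(states):
                update_item(s, y.values[j], grid, config, post_g, post_h)
            engine.process_examinee(y)
        np.testing.assert_allclose(
            engine.beta, np.stack([s.beta_current.beta for s in states]), rtol=1e-10
        )
        np.testing.assert_allclose(
            engine.beta_avg, np.stack([s.beta_avg.beta for s in states]), rtol=1e-10
        )


class TestEngine:
    def test_flat_anchored_items_score_zero(self):
        config = EstimatorConfig(K=7, Q=1)
        params = ItemParamSet.from_arrays(
            np.zeros((4, 2)), free=np.zeros((4, 2), dtype=bool)
        )
        est = OnlineEstimator(params, config)
        for _ in range(5):
            rec = est.process_examinee(ResponseVector([1, 0, 1, 0]))
            np.testing.assert_allclose(rec.eap, 0.0, atol=1e-12)

    def test_identical_records_give_different_updates(self):
        est = OnlineEstimator.with_default_start(3, EstimatorConfig(K=5))
        r1 = est.process_examinee(ResponseVector([1, 0, 1]))
        b1 = est.beta.copy()
        r2 = est.process_examinee(ResponseVector([1, 0, 1]))
        assert r2.step < r1.step  # n-dependent step size
        assert not np.allclose(est.beta - b1, 0)

    def test_trajectory_records_increase_in_n(self, rng):
        est = OnlineEstimator.with_default_start(3, EstimatorConfig(K=5))
        stream = [ResponseVector(rng.integers(0, 2, 3)) for _ in range(20)]
        res = est.run(stream, checkpoints=[5, 10, 20])
        assert [r.n for r in res.records] == [5, 10, 20]
        assert res.eap.shape == (20, 1)

    def test_tsna_identical_to_forced_unit_averaging(self, rng):
        """Non-averaged mode is bitwise the averaged recursion with tau=1."""
        stream = [ResponseVector(rng.integers(0, 2, 5)) for _ in range(60)]
        a = OnlineEstimator.with_default_start(
            5, EstimatorConfig.tsna(K=5)
        ).run(stream)
        b = OnlineEstimator.with_default_start(
            5, EstimatorConfig.tsna(K=5, avg_mode="log", force_tau=1.0)
        ).run(stream)
        assert np.array_equal(a.estimator.beta, b.estimator.beta)
        assert np.array_equal(a.estimator.beta_avg, b.estimator.beta_avg)
        assert np.array_equal(a.estimator.S, b.estimator.S)

    def test_hessian_smallest_eigenvalue_never_decreases(self, rng):
        est = OnlineEstimator.with_default_start(3, EstimatorConfig(K=5))
        prev = np.array(
            [np.linalg.eigvalsh(est.S[j])[0] for j in range(3)]
        )
        for _ in range(40):
            est.process_examinee(ResponseVector(rng.integers(0, 2, 3)))
            cur = np.array(
                [np.linalg.eigvalsh(est.S[j])[0] for j in range(3)]
            )
            assert (cur >= prev - 1e-10).all()
            prev = cur

    def test_stationarity_at_true_parameters(self):
        """The expected gradient vanishes at the data-generating parameters."""
        rng = np.random.default_rng(7)
        J, N, K = 10, 4000, 11
        grid = build_quadrature_grid(K, 1)
        a = rng.uniform(0.5, 2.0, J)
        d = rng.standard_normal(J)
        params = ItemParamSet.from_arrays(np.column_stack([a, d]))
        beta = params.beta_matrix()
        thetas = rng.standard_normal(N)
        from scipy.special import expit

        probs = expit(thetas[:, None] * a + d)
        Y = (rng.random((N, J)) < probs).astype(float)
        total = np.zeros((J, 2))
        for n in range(N):
            y = ResponseVector(Y[n].astype(int))
            post = posterior_node_weights(y, params, grid)
            for j in range(J):
                total[j] += item_gradient(Y[n, j], post, params.items[j], grid)
        mean_grad = total / N
        # Monte Carlo error of a mean of bounded scores at N=4000 is ~0.01
        assert np.max(np.abs(mean_grad)) < 0.05


class TestEAP:
    def test_hand_example(self, two_node_grid, unit_item_set, correct_response):
        eap = eap_ability(correct_response, unit_item_set, two_node_grid)
        assert eap[0] == pytest.approx(SIG1 * 1 + (1 - SIG1) * (-1), abs=1e-9)

    def test_flat_items_give_prior_mean(self, two_node_grid):
        params = ItemParamSet.from_arrays(np.zeros((6, 2)))
        eap = eap_ability(
            ResponseVector([1, 1, 0, 1, 0, 0]), params, two_node_grid
        )
        assert eap[0] == pytest.approx(0.0, abs=1e-12)

    def test_inside_convex_hull(self, rng):
        for _ in range(10):
            params, y, grid = random_instance(rng, Q=1)
            eap = eap_ability(y, params, grid)
            assert grid.nodes.min() <= eap[0] <= grid.nodes.max()


class TestStandardErrors:
    def test_diagonal_inverse(self, unit_item):
        n = 50
        st = OnlineItemState(unit_item, unit_item, n * np.diag([4.0, 4.0]), n=n)
        np.testing.assert_allclose(
            standard_errors(st), [1 / (2 * np.sqrt(n))] * 2
        )

    def test_prior_only_identity(self, unit_item):
        st = OnlineItemState(unit_item, unit_item, np.eye(2), n=1)
        np.testing.assert_allclose(standard_errors(st), [1.0, 1.0])

    def test_engine_ses_shrink_with_n(self, rng):
        est = OnlineEstimator.with_default_start(3, EstimatorConfig(K=5))
        stream = [ResponseVector(rng.integers(0, 2, 3)) for _ in range(200)]
        for y in stream[:50]:
            est.process_examinee(y)
        se50 = est.standard_errors()
        for y in stream[50:]:
            est.process_examinee(y)
        se200 = est.standard_errors()
        assert (se200 < se50).all()

    def test_anchored_entries_are_nan(self):
        config = EstimatorConfig(K=5, Q=2)
        free = np.ones((3, 3), dtype=bool)
        free[0] = False
        est = OnlineEstimator.with_default_start(3, config, free=free)
        rng = np.random.default_rng(0)
        for _ in range(10):
            est.process_examinee(ResponseVector(rng.integers(0, 2, 3)))
        ses = est.standard_errors()
        assert np.isnan(ses[0]).all()
        assert np.isfinite(ses[1:]).all()
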