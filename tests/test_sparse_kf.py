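"""Parameter Kalman filter and pseudo-measurement sparsity stage."""

import numpy as np
import pytest

from ckfsnet import (
    NoiseConfig,
    ParameterBelief,
    PMConfig,
    generate_network,
    kf_param_step,
    pm_iterations,
    select_Ktau,
    sigmoid,
    simulate,
)


def _filter_series(states, observations, n, decoupled, sigma_e2, walk=0.0):
    belief = ParameterBelief.initial(n, decoupled=decoupled, walk_variance=walk)
    F = sigmoid(states)
    for k in range(observations.shape[0]):
        belief = kf_param_step(belief, observations[k], F[k], sigma_e2)
    return belief


class TestKfParamStep:
    def test_zero_innovation_keeps_mean(self, rng):
        belief = ParameterBelief.initial(3, decoupled=False)
        belief.mean = rng.normal(size=9)
        f = sigmoid(rng.normal(size=3))
        y = belief.mean.reshape(3, 3) @ f
        out = kf_param_step(belief, y, f, 0.1)
        np.testing.assert_allclose(out.mean, belief.mean, atol=1e-12)

    def test_scalar_posterior_variance_formula(self):
        # N = 1: var' = P (1 - P f^2 / (P f^2 + sigma_e^2))
        P0, f, se2 = 2.0, 0.7, 0.3
        belief = ParameterBelief(np.array([0.5]), np.array([[P0]]), False)
        out = kf_param_step(belief, np.array([1.0]), np.array([f]), se2)
        expected = P0 * (1 - P0 * f**2 / (P0 * f**2 + se2))
        assert out.covariance[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_convergence_to_truth(self):
        """With persistent excitation and a vanishing noise floor the filter
        recovers the generating weights (batch least-squares oracle)."""
        net = generate_network(4, 6, seed=2)
        data = simulate(net, 15, NoiseConfig(0.0, 0.0), seed=3, n_series=4)
        F = np.vstack([sigmoid(X[:-1]) for X in data.true_states])
        Y = np.vstack([X[1:] for X in data.true_states])
        ls = np.linalg.lstsq(F, Y, rcond=None)[0].T
        np.testing.assert_allclose(ls, net.weights, atol=1e-8)

        belief = ParameterBelief.initial(4, decoupled=False, walk_variance=0.0)
        for k in range(F.shape[0]):
            belief = kf_param_step(belief, Y[k], F[k], 1e-18)
        np.testing.assert_allclose(belief.mean.reshape(4, 4), net.weights, atol=1e-6)

    def test_covariance_trace_non_increasing_without_walk(self, rng):
        belief = ParameterBelief.initial(3, decoupled=False, walk_variance=0.0)
        prev = np.trace(belief.covariance)
        for _ in range(10):
            belief = kf_param_step(belief, rng.normal(size=3),
                                   sigmoid(rng.normal(size=3)), 0.1)
            cur = np.trace(belief.covariance)
            assert cur <= prev + 1e-12
            prev = cur

    def test_decoupled_matches_full_joint(self, rng):
        net = generate_network(5, 10, seed=4)
        data = simulate(net, 30, seed=5)
        X, Y = data.true_states[0], data.series[0]
        full = _filter_series(X[:-1], Y[1:], 5, False, 2e-5)
        dec = _filter_series(X[:-1], Y[1:], 5, True, 2e-5)
        np.testing.assert_allclose(dec.mean, full.mean, atol=1e-8)
        np.testing.assert_allclose(
            dec.covariance, full.covariance_blocks(), atol=1e-8
        )

    def test_accepts_full_regressor_matrix(self, rng):
        from ckfsnet import build_regressor

        belief = ParameterBelief.initial(3, decoupled=False)
        x = rng.normal(size=3)
        y = rng.normal(size=3)
        a = kf_param_step(belief, y, build_regressor(x), 0.1)
        b = kf_param_step(belief, y, sigmoid(x), 0.1)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-13)


class TestPMIterations:
    def test_zero_vector_is_fixed_point(self):
        belief = ParameterBelief.initial(3, decoupled=False)
        out = pm_iterations(belief, PMConfig(5))
        np.testing.assert_array_equal(out.mean, np.zeros(9))

    def test_zero_iterations_is_identity(self, rng):
        belief = ParameterBelief.initial(3, decoupled=False)
        belief.mean = rng.normal(size=9)
        out = pm_iterations(belief, PMConfig(0))
        np.testing.assert_array_equal(out.mean, belief.mean)

    def test_l1_decreases_and_matches_independent_recomputation(self, rng):
        """Each iteration must strictly shrink the l1 norm and agree with a
        step-by-step re-derivation of the pseudo-measurement update."""
        for _ in range(100):
            n = int(rng.integers(2, 5))
            mean = rng.normal(size=n * n) * rng.choice([0.0, 1.0], size=n * n, p=[0.3, 0.7])
            diag = rng.uniform(0.05, 2.0, size=n * n)
            belief = ParameterBelief(mean.copy(), np.diag(diag), False)
            cfg = PMConfig(4, sigma_eps2=100.0)
            out = pm_iterations(belief, cfg)

            b, P = mean.copy(), np.diag(diag).astype(float)
            prev_l1 = np.abs(b).sum()
            for _ in range(cfg.n_iterations):
                s = np.sign(b)
                K = P @ s / (s @ P @ s + cfg.sigma_eps2)
                b = (np.eye(n * n) - np.outer(K, s)) @ b
                P = (np.eye(n * n) - np.outer(K, s)) @ P
                P = 0.5 * (P + P.T)
                l1 = np.abs(b).sum()
                if prev_l1 > 0:
                    assert l1 < prev_l1
                prev_l1 = l1
            np.testing.assert_allclose(out.mean, b, atol=1e-10)
            np.testing.assert_allclose(out.covariance, P, atol=1e-10)

    def test_decoupled_first_iteration_matches_full(self, rng):
        n = 4
        mean = rng.normal(size=n * n)
        blocks = np.stack([np.diag(rng.uniform(0.1, 1.0, n)) for _ in range(n)])
        full_cov = np.zeros((n * n, n * n))
        for i in range(n):
            full_cov[i * n:(i + 1) * n, i * n:(i + 1) * n] = blocks[i]
        cfg = PMConfig(1)
        a = pm_iterations(ParameterBelief(mean.copy(), blocks, True), cfg)
        b = pm_iterations(ParameterBelief(mean.copy(), full_cov, False), cfg)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.covariance, b.covariance_blocks(), atol=1e-12)


class TestSelectKtau:
    @pytest.mark.parametrize("edges,n,expected", [(20, 8, 20), (0, 5, 0), ("auto", 10, 20)])
    def test_values(self, edges, n, expected):
        assert select_Ktau(edges, n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            select_Ktau(-1, 5)
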