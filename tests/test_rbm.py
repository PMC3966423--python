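"""RBM conditionals, free energy, exact-likelihood oracles, and CD-1 training."""

import itertools

import numpy as np
import pytest

import mldbn.rbm as rbm_mod
from mldbn import (
    CDState,
    DimensionError,
    RBMParams,
    RunConfig,
    cd1_step,
    exact_log_likelihood,
    exact_log_likelihood_grad,
    free_energy,
    hidden_probabilities,
    init_rbm,
    train_rbm,
    visible_probabilities,
)


def _random_params(rng, p_vis, p_hid, scale=0.5):
    return RBMParams(
        rng.normal(0, scale, (p_vis, p_hid)),
        rng.normal(0, scale, p_vis),
        rng.normal(0, scale, p_hid),
    )


class TestConditionals:
    def test_zero_parameters_give_half(self, rng):
        params = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        v = (rng.random(4) < 0.5).astype(float)
        np.testing.assert_allclose(hidden_probabilities(v, params), 0.5)
        np.testing.assert_allclose(visible_probabilities(np.ones(3), params), 0.5)

    def test_hand_evaluated_logistic(self):
        params = RBMParams(np.array([[1.0, -1.0], [0.0, 2.0]]), np.zeros(2), np.zeros(2))
        out = hidden_probabilities(np.array([1.0, 0.0]), params)
        np.testing.assert_allclose(out, [0.73106, 0.26894], atol=1e-5)

    def test_hidden_bias_shifts_preactivation_linearly(self, rng):
        params = _random_params(rng, 5, 3)
        v = rng.random(5)
        c = 0.37
        shifted = RBMParams(params.W, params.b_vis, params.b_hid + np.array([0, c, 0]))
        from scipy.special import logit

        pre = logit(hidden_probabilities(v, params))
        pre_shift = logit(hidden_probabilities(v, shifted))
        np.testing.assert_allclose(pre_shift - pre, [0, c, 0], atol=1e-9)

    def test_visible_is_hidden_under_transpose(self, rng):
        params = _random_params(rng, 4, 3)
        swapped = RBMParams(params.W.T, params.b_hid, params.b_vis)
        h = rng.random(3)
        np.testing.assert_allclose(
            visible_probabilities(h, params), hidden_probabilities(h, swapped)
        )

    def test_visible_conditional_matches_joint_enumeration(self, rng):
        # P(v_i=1 | h) from the full Boltzmann joint over a binary h
        params = _random_params(rng, 3, 2)
        h = np.array([1.0, 0.0])
        expected = np.zeros(3)
        weights = []
        states = list(itertools.product((0.0, 1.0), repeat=3))
        for v in states:
            v = np.array(v)
            energy = -(params.b_vis @ v + params.b_hid @ h + v @ params.W @ h)
            weights.append(np.exp(-energy))
        weights = np.array(weights)
        for idx, v in enumerate(states):
            expected += np.array(v) * weights[idx]
        expected /= weights.sum()
        np.testing.assert_allclose(visible_probabilities(h, params), expected, atol=1e-12)

    def test_extreme_preactivations_do_not_overflow(self):
        params = RBMParams(np.array([[700.0], [-700.0]]), np.zeros(2), np.zeros(1))
        out = hidden_probabilities(np.array([1.0, 0.0]), params)
        assert np.all(np.isfinite(out)) and 0 < out[0] <= 1

    def test_shape_mismatch_raises(self, rng):
        params = _random_params(rng, 4, 3)
        with pytest.raises(DimensionError):
            hidden_probabilities(np.zeros(5), params)


class TestFreeEnergy:
    def test_zero_params_closed_form(self):
        params = RBMParams(np.zeros((2, 3)), np.zeros(2), np.zeros(3))
        for v in ([0.0, 0.0], [1.0, 0.0], [1.0, 1.0]):
            assert free_energy(np.array(v), params) == pytest.approx(-3 * np.log(2))

    def test_partition_function_matches_enumeration(self, rng):
        params = _random_params(rng, 4, 3)
        states_v = np.array(list(itertools.product((0.0, 1.0), repeat=4)))
        Z_free = np.exp(-free_energy(states_v, params)).sum()
        Z_joint = 0.0
        for v in states_v:
            for h in itertools.product((0.0, 1.0), repeat=3):
                h = np.array(h)
                Z_joint += np.exp(params.b_vis @ v + params.b_hid @ h + v @ params.W @ h)
        assert Z_free == pytest.approx(Z_joint, rel=1e-10)

    def test_visible_bias_linearity_at_zero_weights(self):
        params = RBMParams(np.zeros((3, 2)), np.array([0.3, -1.2, 0.7]), np.zeros(2))
        v0 = np.zeros(3)
        for i in range(3):
            v1 = v0.copy()
            v1[i] = 1.0
            assert free_energy(v1, params) - free_energy(v0, params) == pytest.approx(
                -params.b_vis[i]
            )


class TestExactLikelihood:
    def test_zero_params_uniform_likelihood(self):
        params = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        X = np.array([[0.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
        assert exact_log_likelihood(X, params) == pytest.approx(-3 * np.log(2))

    def test_gradient_matches_finite_differences(self, rng):
        params = _random_params(rng, 3, 2)
        X = (rng.random((6, 3)) < 0.5).astype(float)
        grad = exact_log_likelihood_grad(X, params)
        eps = 1e-6
        for arr, garr in ((params.W, grad.W), (params.b_vis, grad.b_vis),
                          (params.b_hid, grad.b_hid)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                p1, p2 = params.copy(), params.copy()
                for a1, a2, ref in ((p1.W, p2.W, params.W),
                                    (p1.b_vis, p2.b_vis, params.b_vis),
                                    (p1.b_hid, p2.b_hid, params.b_hid)):
                    if ref is arr:
                        a1[idx] += eps
                        a2[idx] -= eps
                fd = (exact_log_likelihood(X, p1) - exact_log_likelihood(X, p2)) / (2 * eps)
                assert abs(fd - garr[idx]) < 1e-6 * max(1.0, abs(garr[idx]))

    def test_likelihood_invariant_under_hidden_permutation(self, rng):
        params = _random_params(rng, 3, 3)
        X = (rng.random((5, 3)) < 0.5).astype(float)
        perm = [2, 0, 1]
        permuted = RBMParams(params.W[:, perm], params.b_vis, params.b_hid[perm])
        assert exact_log_likelihood(X, params) == pytest.approx(
            exact_log_likelihood(X, permuted), rel=1e-12
        )

    def test_enumeration_guard(self, rng):
        params = _random_params(rng, 12, 8, scale=0.01)
        with pytest.raises(DimensionError, match="refused"):
            exact_log_likelihood(np.zeros((1, 12)), params)


class TestCD1:
    def test_zero_learning_rate_leaves_params(self, rng, fast_cfg):
        import dataclasses

        params = _random_params(rng, 4, 3)
        cfg = dataclasses.replace(fast_cfg, learning_rate=1e-300)  # lr must be > 0
        state = CDState.zeros(params)
        batch = (rng.random((5, 4)) < 0.5).astype(float)
        new_params, new_state = cd1_step(batch, params, state, cfg, rng)
        np.testing.assert_allclose(new_params.W, params.W, atol=1e-290)
        np.testing.assert_allclose(new_state.velocity_W, 0.0, atol=1e-290)

    def test_momentum_decays_velocity_without_gradient(self, rng):
        # a batch equal to its own fixed point yields (almost) pure momentum decay
        params = RBMParams(np.zeros((2, 1)), np.zeros(2), np.zeros(1))
        cfg = RunConfig(layer_sizes=[1], learning_rate=1e-300, momentum=0.5,
                        weight_decay=0.0)
        state = CDState(np.full((2, 1), 0.8), np.zeros(2), np.zeros(1), epoch=0)
        _, new_state = cd1_step(np.array([[0.0, 1.0]]), params, state, cfg, rng)
        np.testing.assert_allclose(new_state.velocity_W, 0.4 * np.ones((2, 1)), atol=1e-290)

    def test_mean_update_aligns_with_exact_gradient(self, rng):
        params = _random_params(rng, 3, 2, scale=0.3)
        X = (rng.random((8, 3)) < 0.5).astype(float)
        grad = exact_log_likelihood_grad(X, params)
        cfg = RunConfig(layer_sizes=[2], learning_rate=1.0, momentum=0.0,
                        weight_decay=0.0, batch_size=10**9)
        big = np.tile(X, (1250, 1))  # 10,000 chains
        new_params, _ = cd1_step(big, params, CDState.zeros(params), cfg, rng)
        upd = np.concatenate([
            (new_params.W - params.W).ravel(),
            new_params.b_vis - params.b_vis,
            new_params.b_hid - params.b_hid,
        ])
        exact = np.concatenate([grad.W.ravel(), grad.b_vis, grad.b_hid])
        cos = upd @ exact / (np.linalg.norm(upd) * np.linalg.norm(exact))
        assert cos > 0.9

    def test_nonfinite_update_raises_with_epoch(self, rng):
        params = RBMParams(np.full((2, 1), 1e308), np.zeros(2), np.zeros(1))
        cfg = RunConfig(layer_sizes=[1], learning_rate=1.0, weight_decay=10.0)
        state = CDState.zeros(params)
        state.epoch = 5
        with pytest.raises(FloatingPointError, match="epoch 5"):
            cd1_step(np.ones((1, 2)), params, state, cfg, rng)


class TestTrainRBM:
    def test_zero_epochs_returns_initial_params(self, rng):
        cfg = RunConfig(layer_sizes=[3], pretrain_epochs=0)
        X = (rng.random((10, 4)) < 0.5).astype(float)
        seed_state = rng.bit_generator.state
        params = train_rbm(X, 3, cfg, rng)
        fresh = np.random.default_rng()
        fresh.bit_generator.state = seed_state
        expected = init_rbm(4, 3, fresh)
        np.testing.assert_array_equal(params.W, expected.W)

    def test_batch_arithmetic(self, rng, monkeypatch):
        sizes = []
        original = rbm_mod.cd1_step

        def counting(batch, *args, **kwargs):
            sizes.append(batch.shape[0])
            return original(batch, *args, **kwargs)

        monkeypatch.setattr(rbm_mod, "cd1_step", counting)
        cfg = RunConfig(layer_sizes=[2], pretrain_epochs=1, batch_size=100)
        X = (rng.random((250, 5)) < 0.5).astype(float)
        train_rbm(X, 2, cfg, rng)
        assert sizes == [100, 100, 50]

    def test_reconstruction_error_decreases_on_structured_data(self):
        # correlated binary data: two latent prototypes plus flip noise
        gen = np.random.default_rng(99)
        proto = (gen.random((2, 20)) < 0.5).astype(float)
        X = proto[gen.integers(0, 2, 500)]
        flip = gen.random((500, 20)) < 0.05
        X = np.where(flip, 1 - X, X)
        cfg = RunConfig(layer_sizes=[8], pretrain_epochs=30, batch_size=100, seed=0)
        _, history = train_rbm(X, 8, cfg, np.random.default_rng(0), return_history=True)
        assert history[-1] < history[0]

    def test_training_is_bit_reproducible(self, fast_cfg):
        X = (np.random.default_rng(3).random((40, 6)) < 0.5).astype(float)
        a = train_rbm(X, 4, fast_cfg, np.random.default_rng(11))
        b = train_rbm(X, 4, fast_cfg, np.random.default_rng(11))
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b_hid, b.b_hid)
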