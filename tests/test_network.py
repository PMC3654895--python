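import math

import numpy as np
import pytest

from annbm.network import (Network, NetworkConfig, select_hidden_size, sigmoid,
                           train)


def make_net(n_input=4, n_hidden=3, seed=0, **kw):
    return Network(NetworkConfig(n_input=n_input, n_hidden=n_hidden,
                                 seed=seed, **kw))


def finite_difference_gradients(net, X, t, h=1e-6):
    """Central finite differences of E = sum (o-t)^2 / (2N)."""
    def loss():
        o = net.forward_batch(X)
        return float(np.sum((o - np.asarray(t)) ** 2) / (2 * len(t)))

    grads = []
    for W in (net.weights_ih, net.weights_ho):
        g = np.zeros_like(W)
        it = np.nditer(W, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = W[idx]
            W[idx] = orig + h
            up = loss()
            W[idx] = orig - h
            down = loss()
            W[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads.append(g)
    return grads


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == 0.5

    @pytest.mark.parametrize("x", [-3.0, -0.5, 0.7, 5.0])
    def test_odd_symmetry_about_half(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-15)

    def test_extreme_inputs_stay_in_open_interval(self):
        with np.errstate(over="raise"):
            lo, hi = sigmoid(-1000.0), sigmoid(1000.0)
        assert 0.0 <= lo < 1e-300 or lo == 0.0  # underflow to 0 acceptable
        assert hi == 1.0 or hi < 1.0
        assert np.isfinite([lo, hi]).all()


class TestForward:
    def test_zero_weights_give_half(self):
        net = make_net()
        net.weights_ih[:] = 0
        net.weights_ho[:] = 0
        assert net.forward([1.0, -2.0, 3.0, 0.5]) == 0.5

    def test_matches_hand_computation_on_tiny_net(self):
        net = make_net(n_input=2, n_hidden=2)
        net.weights_ih = np.array([[0.5, -0.3, 0.1],
                                   [-0.2, 0.4, -0.6]])
        net.weights_ho = np.array([[0.7, -0.5, 0.2]])
        x = [1.0, 2.0]
        h1 = 1 / (1 + math.exp(-(0.5 * 1 - 0.3 * 2 + 0.1)))
        h2 = 1 / (1 + math.exp(-(-0.2 * 1 + 0.4 * 2 - 0.6)))
        expected = 1 / (1 + math.exp(-(0.7 * h1 - 0.5 * h2 + 0.2)))
        assert net.forward(x) == pytest.approx(expected, abs=1e-12)

    def test_hidden_unit_permutation_invariance(self):
        net = make_net(n_input=3, n_hidden=4, seed=2)
        x = [0.3, -1.0, 2.0]
        before = net.forward(x)
        perm = [2, 0, 3, 1]
        net.weights_ih = net.weights_ih[perm]
        net.weights_ho = np.hstack([net.weights_ho[:, perm],
                                    net.weights_ho[:, -1:]])
        assert net.forward(x) == pytest.approx(before, abs=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="input size"):
            make_net(n_input=4).forward([1.0, 2.0])

    def test_output_bounded_for_wild_weights(self):
        net = make_net()
        net.weights_ih[:] = 1e6
        net.weights_ho[:] = -1e6
        assert 0.0 <= net.forward([1e3] * 4) <= 1.0


class TestGradients:
    def test_zero_error_batch_gives_zero_gradients(self):
        net = make_net(seed=3)
        X = np.random.default_rng(0).normal(size=(5, 4))
        t = net.forward_batch(X)  # targets equal outputs
        g_ih, g_ho = net.gradients(X, t)
        assert np.allclose(g_ih, 0) and np.allclose(g_ho, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = make_net(n_input=6, n_hidden=4, seed=seed)
        X = rng.normal(size=(5, 6))
        t = rng.uniform(0, 1, 5)
        g_ih, g_ho = net.gradients(X, t)
        fd_ih, fd_ho = finite_difference_gradients(net, X, t)
        for a, b in ((g_ih, fd_ih), (g_ho, fd_ho)):
            denom = np.maximum(np.abs(b), 1e-8)
            assert np.max(np.abs(a - b) / denom) < 1e-5

    def test_duplicated_batch_unchanged_by_mean_convention(self):
        rng = np.random.default_rng(4)
        net = make_net(seed=4)
        X = rng.normal(size=(6, 4))
        t = rng.uniform(0, 1, 6)
        g1 = net.gradients(X, t)
        g2 = net.gradients(np.vstack([X, X]), np.hstack([t, t]))
        for a, b in zip(g1, g2):
            np.testing.assert_allclose(a, b, atol=1e-15)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_net().gradients(np.empty((0, 4)), np.empty(0))


class TestRprop:
    def test_step_size_grows_by_eta_plus_on_same_sign(self):
        net = make_net(n_input=2, n_hidden=2)
        g = (np.ones_like(net.weights_ih), np.ones_like(net.weights_ho))
        net.rprop_step(*g)  # first step: prev sign 0, delta unchanged
        assert np.allclose(net.delta_ih, 0.1)
        net.rprop_step(*g)  # same sign: grow
        assert np.allclose(net.delta_ih, 0.1 * 1.2)
        net.rprop_step(*g)
        assert np.allclose(net.delta_ih, 0.1 * 1.2 * 1.2)

    def test_step_size_shrinks_by_eta_minus_on_sign_flip(self):
        net = make_net(n_input=2, n_hidden=2)
        g_pos = (np.ones_like(net.weights_ih), np.ones_like(net.weights_ho))
        g_neg = tuple(-g for g in g_pos)
        net.rprop_step(*g_pos)
        net.rprop_step(*g_neg)  # flip
        assert np.allclose(net.delta_ih, 0.1 * 0.5)

    def test_weight_moves_against_gradient_sign_by_delta(self):
        net = make_net(n_input=2, n_hidden=2)
        w0 = net.weights_ih.copy()
        g = (np.ones_like(net.weights_ih), np.zeros_like(net.weights_ho))
        net.rprop_step(*g)
        np.testing.assert_allclose(net.weights_ih, w0 - 0.1)

    def test_zero_gradient_leaves_weight_and_delta_unchanged(self):
        net = make_net(n_input=2, n_hidden=2)
        w0 = net.weights_ih.copy()
        zeros = (np.zeros_like(net.weights_ih), np.zeros_like(net.weights_ho))
        net.rprop_step(*zeros)
        np.testing.assert_array_equal(net.weights_ih, w0)
        assert np.allclose(net.delta_ih, 0.1)

    def test_delta_clamped_to_bounds(self):
        net = make_net(n_input=2, n_hidden=2, delta_max=0.3)
        g = (np.ones_like(net.weights_ih), np.ones_like(net.weights_ho))
        for _ in range(30):
            net.rprop_step(*g)
        assert np.allclose(net.delta_ih, 0.3)
        g_flip = g
        for _ in range(100):
            g_flip = tuple(-x for x in g_flip)
            net.rprop_step(*g_flip)
        assert np.all(net.delta_ih >= net.config.delta_min)
        assert np.all(net.delta_ih <= net.config.delta_max)

    def test_sign_memory_cleared_after_flip(self):
        # after a flip the next same-sign step must not shrink again
        net = make_net(n_input=2, n_hidden=2)
        ones = (np.ones_like(net.weights_ih), np.ones_like(net.weights_ho))
        neg = tuple(-x for x in ones)
        net.rprop_step(*ones)
        net.rprop_step(*neg)          # flip: delta 0.05, memory cleared
        d_after_flip = net.delta_ih.copy()
        net.rprop_step(*ones)         # prev sign 0: delta unchanged
        np.testing.assert_allclose(net.delta_ih, d_after_flip)


def xor_data():
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    t = np.array([0.1, 0.9, 0.9, 0.1])
    return X, t


class TestTrain:
    def test_learns_xor_style_mapping(self):
        X, t = xor_data()
        cfg = NetworkConfig(n_input=2, n_hidden=4, max_epochs=500,
                            patience=500, val_fraction=0.0, seed=1)
        net, trace = train(X, t, cfg)
        assert net.mse(X, t) < 0.01
        assert len(trace.train_mse) <= 500

    def test_fixed_seed_reproduces_trajectory(self):
        X, t = xor_data()
        cfg = NetworkConfig(n_input=2, n_hidden=4, max_epochs=50,
                            patience=50, val_fraction=0.0, seed=7)
        net1, trace1 = train(X, t, cfg)
        net2, trace2 = train(X, t, cfg)
        assert trace1.train_mse == trace2.train_mse
        np.testing.assert_array_equal(net1.weights_ih, net2.weights_ih)
        np.testing.assert_array_equal(net1.weights_ho, net2.weights_ho)

    def test_training_reduces_mse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        t = sigmoid(X @ rng.normal(size=5))
        cfg = NetworkConfig(n_input=5, n_hidden=4, max_epochs=100,
                            patience=100, seed=3)
        net, trace = train(X, t, cfg)
        assert trace.train_mse[-1] < trace.train_mse[0]

    def test_degenerate_targets_warn_but_train(self, caplog):
        X = np.random.default_rng(0).normal(size=(10, 3))
        t = np.full(10, 0.5)
        cfg = NetworkConfig(n_input=3, n_hidden=2, max_epochs=10, seed=0)
        import logging
        with caplog.at_level(logging.WARNING):
            train(X, t, cfg)
        assert "identical" in caplog.text

    def test_targets_outside_unit_interval_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="targets"):
            train(X, np.array([0.0, 0.5, 1.2, 0.1]),
                  NetworkConfig(n_input=2))

    def test_early_stopping_respects_patience(self):
        X, t = xor_data()
        cfg = NetworkConfig(n_input=2, n_hidden=3, max_epochs=2000,
                            patience=10, val_fraction=0.25, seed=5)
        net, trace = train(X, t, cfg)
        assert trace.stop_reason in ("patience", "max_epochs")
        if trace.stop_reason == "patience":
            assert len(trace.val_mse) <= trace.best_epoch + 11


class TestSelectHiddenSize:
    def test_singleton_candidate_returned(self):
        X, t = xor_data()
        cfg = NetworkConfig(n_input=2, max_epochs=20, patience=20, seed=0)
        assert select_hidden_size(X, t, cfg, candidates=[5]) == 5

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_hidden_size(*xor_data(),
                               NetworkConfig(n_input=2), candidates=[])

    def test_returns_argmin_of_validation_mse(self):
        # independent enumeration oracle: train every candidate ourselves
        # and check the selection is the validation-MSE argmin (ties to
        # the smallest size)
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        t = sigmoid(X @ np.array([1.0, -0.5, 0.3, 0.8]))
        base = dict(n_input=4, max_epochs=60, patience=60, seed=11)
        candidates = [2, 3, 9, 12]
        val = {}
        for h in candidates:
            _, trace = train(X, t, NetworkConfig(n_hidden=h, **base))
            val[h] = min(trace.val_mse)
        expected = min(candidates, key=lambda h: (val[h], h))
        got = select_hidden_size(X, t, NetworkConfig(**base),
                                 candidates=candidates)
        assert got == expected

    def test_default_range_enumerates_2_to_12(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 3))
        t = sigmoid(X @ np.array([0.5, -1.0, 0.25]))
        seen = []
        import annbm.network as netmod
        orig = netmod.train

        def spy(X_, t_, cfg):
            seen.append(cfg.n_hidden)
            return orig(X_, t_, cfg)

        netmod.train = spy
        try:
            select_hidden_size(X, t, NetworkConfig(n_input=3, max_epochs=5,
                                                   patience=5, seed=0))
        finally:
            netmod.train = orig
        assert seen == list(range(2, 13))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"eta_plus": 0.9}, {"eta_minus": 1.1},
        {"delta_init": 100.0}, {"rprop_variant": "bogus"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            NetworkConfig(n_input=4, **kw)


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        net = make_net(n_input=5, n_hidden=3, seed=9)
        payload = net.to_dict()
        back = Network.from_dict(payload)
        np.testing.assert_array_equal(back.weights_ih, net.weights_ih)
        np.testing.assert_array_equal(back.weights_ho, net.weights_ho)
        x = np.random.default_rng(1).normal(size=5)
        assert back.forward(x) == net.forward(x)
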