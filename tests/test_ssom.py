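import numpy as np
import pytest
from scipy.spatial.distance import cdist

import cogtrace as ct
from cogtrace import SSOMConfig, ValidationError
from cogtrace.ssom import _init_network


def tiny_net(w_in, w_out, grid_shape=(1, 2), **cfg):
    config = SSOMConfig(grid_shape=grid_shape, **cfg)
    rows, cols = grid_shape
    grid = np.stack(np.meshgrid(np.arange(rows), np.arange(cols),
                                indexing="ij"), axis=-1).reshape(-1, 2)
    return ct.SSOMNetwork(w_in=np.asarray(w_in, float),
                          w_out=np.asarray(w_out, float),
                          grid=grid, config=config)


class TestFindWinner:
    def test_zero_distance_winner(self):
        net = tiny_net([[0, 1], [0, 1]], [[1, 0], [0, 1]])
        g, d = ct.find_winner([1, 1], net)
        assert g == 1 and d[1] == 0

    def test_direct_two_neuron_case(self):
        net = tiny_net([[0, 1], [0, 1]], [[1, 0], [0, 1]])
        g, _ = ct.find_winner([0.9, 0.9], net)
        assert g == 1

    def test_matches_brute_force_distance_scan(self, rng):
        w_in = rng.random((20, 100))
        net = tiny_net(w_in, rng.random((100, 8)), grid_shape=(10, 10))
        xs = rng.random((50, 20))
        oracle = np.argmin(cdist(xs, w_in.T), axis=1)
        winners = [ct.find_winner(x, net)[0] for x in xs]
        assert winners == oracle.tolist()

    def test_nan_rejected(self):
        net = tiny_net([[0, 1], [0, 1]], [[1, 0], [0, 1]])
        with pytest.raises(ValidationError):
            ct.find_winner([np.nan, 0], net)


class TestPredictedLabel:
    def test_one_hot_row(self):
        net = tiny_net([[0, 1], [0, 1]], [[0, 0, 1, 0], [1, 0, 0, 0]])
        assert ct.predicted_label(0, net) == 2

    def test_tie_breaks_to_lowest_class(self):
        net = tiny_net([[0, 1], [0, 1]], [[0.3, 0.3, 0.3], [0.3, 0.3, 0.3]])
        assert ct.predicted_label(0, net) == 0


class TestUpdateWeights:
    def constant_cfg(self, **kw):
        return dict(eta1=(0.5, 0.5), eta2=(0.5, 0.5), radius_start=0.0, **kw)

    def test_match_pulls_input_weight(self):
        # W' = W + eta1 (x - W): 0.2 + 0.5*(1.0 - 0.2) = 0.6
        net = tiny_net([[0.2, 0.9]], [[1, 0], [0, 1]], grid_shape=(1, 2),
                       **self.constant_cfg())
        ct.update_weights(net, [1.0], [1.0, 0.0], 0, t=0, total_steps=10)
        assert net.w_in[0, 0] == pytest.approx(0.6)
        assert net.w_in[0, 1] == pytest.approx(0.9)  # outside radius 0

    def test_mismatch_with_negative_mu_repels_output(self):
        # winner 0 predicts class 1 (argmax [0.8, 0.9]); true class is 0, so
        # the mismatch branch fires: W' = W + mu*eta2*(y - W)
        #   -> 0.8 + (-0.5)(0.5)(1.0 - 0.8) = 0.75
        net = tiny_net([[0.2, 0.9]], [[0.8, 0.9], [0.5, 0.4]],
                       grid_shape=(1, 2), mu=-0.5, **self.constant_cfg())
        ct.update_weights(net, [1.0], [1.0, 0.0], 0, t=0, total_steps=10)
        assert net.w_out[0, 0] == pytest.approx(0.75)

    def test_zero_learning_not_possible_but_tiny_rate_is_stable(self):
        net = tiny_net([[0.2, 0.9]], [[1, 0], [0, 1]], grid_shape=(1, 2),
                       eta1=(1e-9, 1e-9), eta2=(1e-9, 1e-9), radius_start=0.0)
        before = net.w_in.copy()
        ct.update_weights(net, [1.0], [1.0, 0.0], 0, t=0, total_steps=10)
        assert np.allclose(net.w_in, before, atol=1e-8)

    def test_match_update_stays_in_convex_hull(self, rng):
        # Eq. is a convex combination when 0 < eta <= 1 and mu > 0
        cfg = SSOMConfig(grid_shape=(4, 4), iterations=2)
        net = _init_network(6, 4, cfg, rng)
        X = rng.integers(0, 2, size=(30, 6)).astype(float)
        y = rng.integers(0, 4, size=30)
        onehot = np.eye(4)
        for t, i in enumerate(rng.integers(0, 30, size=200)):
            g, _ = ct.find_winner(X[i], net)
            ct.update_weights(net, X[i], onehot[y[i]], g, t, 200)
        assert net.w_in.min() >= -1e-9 and net.w_in.max() <= 1 + 1e-9


class TestTrain:
    def test_separable_data_reaches_perfect_accuracy(self, q_emp):
        X, y = ct.build_training_set(q_emp, size=80)
        cfg = SSOMConfig(grid_shape=(9, 9), iterations=3)
        for seed in range(5):
            net = ct.train(X, y, cfg, seed=seed)
            assert net.history[-1] == 1.0

    def test_colliding_pair_caps_uniform_accuracy(self, q3):
        X, y = ct.build_training_set(q3, size=8 * 16)
        cfg = SSOMConfig(grid_shape=(10, 10), iterations=4)
        net = ct.train(X, y, cfg, seed=0)
        assert net.history[-1] <= 15 / 16 + 1e-9

    def test_determinism_under_seed(self, q_emp):
        X, y = ct.build_training_set(q_emp, size=40)
        cfg = SSOMConfig(grid_shape=(6, 6), iterations=2)
        a = ct.train(X, y, cfg, seed=3)
        b = ct.train(X, y, cfg, seed=3)
        assert np.array_equal(a.w_in, b.w_in)
        assert np.array_equal(a.w_out, b.w_out)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            ct.train(np.empty((0, 4)), np.empty(0, dtype=int),
                     SSOMConfig(grid_shape=(3, 3)))


class TestClassify:
    def test_training_set_consistency(self, emp_net):
        net, X, y = emp_net
        assert np.array_equal(ct.classify(X, net), y)

    def test_noise_free_responses_recover_true_patterns(self, q_emp, emp_net, rng):
        net, _, _ = emp_net
        profiles = rng.integers(0, 2, size=(100, 3))
        responses = ct.ideal_response(profiles, q_emp)
        est = ct.classify(responses, net)
        assert np.array_equal(est, ct.encode_patterns(profiles))

    def test_all_zero_row_maps_to_zero_pattern(self, emp_net):
        net, _, _ = emp_net
        assert ct.classify(np.zeros((1, 8)), net)[0] == 0

    def test_matches_nearest_ideal_vector_oracle(self, q_emp, emp_net, rng):
        net, _, _ = emp_net
        ideal = q_emp.ideal_responses()
        noisy = rng.integers(0, 2, size=(300, 8))
        est = ct.classify(noisy, net)
        d = cdist(noisy, ideal, metric="cityblock")
        # oracle agreement wherever the nearest ideal vector is unique
        unique = (d == d.min(axis=1, keepdims=True)).sum(axis=1) == 1
        assert np.array_equal(est[unique], np.argmin(d, axis=1)[unique])

    def test_column_mismatch_rejected(self, emp_net):
        net, _, _ = emp_net
        with pytest.raises(ValidationError):
            ct.classify(np.zeros((2, 5)), net)


class TestSelectIterations:
    def test_separable_data_stabilizes_immediately(self, q_emp):
        X, y = ct.build_training_set(q_emp, size=40)
        cfg = SSOMConfig(grid_shape=(9, 9), iterations=1)
        assert ct.select_iterations(X, y, cfg, patience=2, cap=6, seed=0) <= 3

    def test_k3_20_items_stabilizes_after_few_passes(self, q3, rng):
        weights = ct.pattern_distribution([0.4, 0.4, 0.2], 0.5)
        X, y = ct.build_training_set(q3, pattern_weights=weights, size=300,
                                     rng=rng)
        cfg = SSOMConfig(grid_shape=(10, 10), iterations=1)
        assert ct.select_iterations(X, y, cfg, patience=2, cap=8, seed=0) <= 4


def test_network_serialization_roundtrip(tmp_path, emp_net):
    net, X, _ = emp_net
    path = tmp_path / "net.npz"
    net.save(path)
    loaded = ct.SSOMNetwork.load(path)
    assert np.array_equal(loaded.w_in, net.w_in)
    assert loaded.config == net.config
    assert np.array_equal(ct.classify(X, loaded), ct.classify(X, net))
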