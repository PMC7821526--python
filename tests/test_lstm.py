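"""Stack LSTM: forward equivalence with a direct recursion, exact gradients,
output contracts, training determinism and hyper-parameter search."""

import numpy as np
import pytest

from lfpdecode import (
    CellState,
    ForceLSTM,
    HyperParams,
    LSTMLayerWeights,
    NetworkParams,
    lstm_cell_forward,
    lstm_layer_forward,
    network_forward,
    train_network,
    tune_hyperparameters,
)
from lfpdecode.lstm import (
    _draw_masks,
    _loss_and_grads,
    init_params,
    load_params,
    save_params,
)

from _oracles import lstm_direct_recursion


def random_layer(rng, units, input_dim, scale=0.5, use_bias=False):
    cols = units + input_dim + (1 if use_bias else 0)
    return LSTMLayerWeights(
        *(scale * rng.standard_normal((units, cols)) for _ in range(4)),
        use_bias=use_bias,
    )


class TestCellForward:
    def test_zero_weights_halve_gates(self):
        w = LSTMLayerWeights(*(np.zeros((2, 5)) for _ in range(4)))
        c0 = np.array([0.8, -0.4])
        out = lstm_cell_forward(np.zeros(3), CellState(y=np.zeros(2), C=c0), w)
        # sigmoid(0) = 1/2, tanh(0) = 0: C = c0/2, y = C/2
        np.testing.assert_allclose(out.C, 0.5 * c0)
        np.testing.assert_allclose(out.y, 0.25 * c0)

    def test_zero_state_zero_weights(self):
        w = LSTMLayerWeights(*(np.zeros((2, 5)) for _ in range(4)))
        out = lstm_cell_forward(np.zeros(3), CellState(np.zeros(2), np.zeros(2)), w)
        np.testing.assert_array_equal(out.y, 0.0)
        np.testing.assert_array_equal(out.C, 0.0)

    def test_fixed_small_instance_matches_hand_recursion(self):
        # 2 units over 3 inputs, weights frozen in the fixture
        rng = np.random.default_rng(12345)
        w = random_layer(rng, 2, 3)
        X = rng.standard_normal((4, 3))
        out = np.stack(
            [
                lstm_layer_forward(X, w)[t]
                for t in range(4)
            ]
        )
        ref = lstm_direct_recursion(X, w.W_c, w.W_u, w.W_f, w.W_o)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_dimension_mismatch(self):
        w = LSTMLayerWeights(*(np.zeros((2, 5)) for _ in range(4)))
        with pytest.raises(ValueError):
            lstm_cell_forward(np.zeros(4), CellState(np.zeros(2), np.zeros(2)), w)


class TestLayerForward:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("variant", ["paper", "standard"])
    def test_matches_direct_recursion(self, seed, variant):
        rng = np.random.default_rng(seed)
        units = int(rng.integers(1, 5))
        d = int(rng.integers(1, 6))
        T = int(rng.integers(1, 12))
        w = random_layer(rng, units, d, use_bias=variant == "standard")
        X = rng.standard_normal((T, d))
        out = lstm_layer_forward(X, w, variant=variant)
        ref = lstm_direct_recursion(
            X, w.W_c, w.W_u, w.W_f, w.W_o, variant=variant, bias=w.use_bias
        )
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_single_step_equals_cell(self, rng):
        w = random_layer(rng, 3, 4)
        x = rng.standard_normal((1, 4))
        layer_out = lstm_layer_forward(x, w)
        cell_out = lstm_cell_forward(x[0], CellState(np.zeros(3), np.zeros(3)), w)
        np.testing.assert_allclose(layer_out[0], cell_out.y, atol=1e-14)

    def test_all_ones_masks_are_identity(self, rng):
        w = random_layer(rng, 3, 4)
        X = rng.standard_normal((6, 4))
        plain = lstm_layer_forward(X, w)
        masked = lstm_layer_forward(X, w, dropout_masks=(np.ones(4), np.ones(3)))
        np.testing.assert_allclose(plain, masked, atol=1e-14)

    def test_saturated_forget_gate_suppresses_history(self, rng):
        w = random_layer(rng, 2, 3)
        w.W_f[:] = 0.0
        w.W_f[:, -1] = -50.0  # forget gate ~0 whenever the last input is ~1
        X = rng.standard_normal((10, 3))
        X[:, -1] = 1.0
        out = lstm_layer_forward(X, w)
        ref = lstm_direct_recursion(X, w.W_c, w.W_u, w.W_f, w.W_o)
        np.testing.assert_allclose(out, ref, atol=1e-12)


class TestNetworkForward:
    def make_params(self, rng, variant="paper"):
        return init_params(n_features=6, units=(4, 3), seed=int(rng.integers(1e6)), variant=variant)

    def test_relu_floor_and_offset(self, rng):
        p = self.make_params(rng)
        X = rng.standard_normal((30, 6))
        p.dense_w[:] = 0.0
        p.dense_b = -1.0
        np.testing.assert_array_equal(network_forward(X, p), 0.0)
        p.dense_b = 0.2
        np.testing.assert_allclose(network_forward(X, p), 0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_predictions_always_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        p = self.make_params(rng)
        X = 3.0 * rng.standard_normal((30, 6))
        pred = network_forward(X, p)
        assert pred.shape == (30,)
        assert np.all(pred >= 0.0)

    def test_causality_no_peeking(self, rng):
        p = self.make_params(rng)
        X = rng.standard_normal((30, 6))
        base = network_forward(X, p)
        X2 = X.copy()
        X2[20:] = rng.standard_normal((10, 6))  # future perturbation
        pred2 = network_forward(X2, p)
        np.testing.assert_array_equal(base[:20], pred2[:20])

    def test_gate_range_strictly_open(self, rng):
        from lfpdecode.lstm import _sigmoid

        x = rng.standard_normal(1000) * 8
        g = _sigmoid(x)
        assert np.all(g > 0.0) and np.all(g < 1.0)


class TestGradients:
    @pytest.mark.parametrize("variant", ["paper", "standard"])
    @pytest.mark.parametrize("with_dropout", [False, True])
    def test_bptt_matches_finite_differences(self, variant, with_dropout):
        rng = np.random.default_rng(99)
        params = init_params(n_features=4, units=(3, 2), seed=5, variant=variant, l2_lambda=0.1)
        X = rng.standard_normal((2, 6, 4))
        Y = np.abs(rng.standard_normal((2, 6)))
        if with_dropout:
            hp = HyperParams(0.3, 0.3, 0.2, 0.2)
            masks = _draw_masks(rng, 2, params, hp)
        else:
            masks = {}
        _, grads = _loss_and_grads(X, Y, params, masks)

        def loss_fn():
            l, _ = _loss_and_grads(X, Y, params, masks)
            return l

        eps = 1e-6
        # spot-check entries of every weight tensor
        for name, arr, g in [
            ("l1.W_c", params.layer1.W_c, grads["W1"][:3]),
            ("l1.W_o", params.layer1.W_o, grads["W1"][9:]),
            ("l2.W_f", params.layer2.W_f, grads["W2"][4:6]),
            ("dense_w", params.dense_w, grads["dense_w"]),
        ]:
            from itertools import islice

            for idx in islice(np.ndindex(*arr.shape), 6):
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss_fn()
                arr[idx] = orig - eps
                lm = loss_fn()
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name

    def test_dense_bias_gradient(self):
        rng = np.random.default_rng(3)
        params = init_params(n_features=4, units=(3, 2), seed=5)
        X = rng.standard_normal((2, 6, 4))
        Y = np.abs(rng.standard_normal((2, 6)))
        _, grads = _loss_and_grads(X, Y, params, {})
        eps = 1e-6
        params.dense_b += eps
        lp, _ = _loss_and_grads(X, Y, params, {})
        params.dense_b -= 2 * eps
        lm, _ = _loss_and_grads(X, Y, params, {})
        assert grads["dense_b"] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestTraining:
    def tiny_trials(self, rng, n=8, T=12, d=5):
        trials = []
        beta = rng.standard_normal(d)
        for _ in range(n):
            X = rng.standard_normal((T, d))
            y = np.maximum(X @ beta * 0.2 + 0.3, 0.0)
            trials.append((X, y))
        return trials

    def test_deterministic_given_seed(self, rng):
        trials = self.tiny_trials(rng)
        hp = HyperParams(n_epochs=3, batch_size=4)
        p1, t1 = train_network(trials, hp, seed=11, units=(4, 3))
        p2, t2 = train_network(trials, hp, seed=11, units=(4, 3))
        np.testing.assert_array_equal(p1.layer1.W_c, p2.layer1.W_c)
        np.testing.assert_array_equal(p1.dense_w, p2.dense_w)
        assert t1 == t2

    def test_zero_learning_rate_is_inert(self, rng):
        trials = self.tiny_trials(rng)
        hp = HyperParams(learning_rate=0.0, n_epochs=3, batch_size=4,
                         dropout_l1_forward=0.0, dropout_l1_recurrent=0.0,
                         dropout_l2_forward=0.0, dropout_l2_recurrent=0.0)
        p, trace = train_network(trials, hp, seed=1, units=(4, 3))
        ref = init_params(5, units=(4, 3), seed=int(np.random.default_rng(1).integers(2**31)))
        np.testing.assert_array_equal(p.layer1.W_c, ref.layer1.W_c)
        assert len(set(np.round(trace, 12))) == 1  # constant loss trace

    def test_loss_decreases_on_learnable_problem(self, rng):
        trials = self.tiny_trials(rng, n=12)
        hp = HyperParams(n_epochs=60, batch_size=6, learning_rate=0.003,
                         dropout_l1_forward=0.0, dropout_l1_recurrent=0.0,
                         dropout_l2_forward=0.0, dropout_l2_recurrent=0.0)
        _, trace = train_network(trials, hp, seed=2, units=(4, 3))
        assert trace[-1] < 0.85 * trace[0]
        # steady descent, not a lucky endpoint
        assert np.mean(trace[-10:]) < np.mean(trace[:10])

    def test_epoch_cap(self, rng):
        trials = self.tiny_trials(rng)
        _, trace = train_network(trials, HyperParams(n_epochs=100), seed=0,
                                 units=(4, 3), epoch_cap=2)
        assert len(trace) == 2


class TestTuning:
    def one_point_grid(self, **over):
        grid = {
            "dropout_l1_forward": (0.0,),
            "dropout_l1_recurrent": (0.0,),
            "dropout_l2_forward": (0.0,),
            "dropout_l2_recurrent": (0.0,),
            "l2_lambda": (0.0,),
            "learning_rate": (0.002,),
            "batch_size": (4,),
            "n_epochs": (3,),
        }
        grid.update(over)
        return grid

    def test_single_point_grid_returned_without_search(self, rng):
        trials = TestTraining().tiny_trials(rng)
        hp, log = tune_hyperparameters(trials, grid=self.one_point_grid(), budget=5, seed=0)
        assert hp.learning_rate == 0.002 and hp.n_epochs == 3
        assert log == []

    def test_budget_one_evaluates_single_config(self, rng):
        trials = TestTraining().tiny_trials(rng)
        grid = self.one_point_grid(learning_rate=(0.001, 0.003))
        hp, log = tune_hyperparameters(trials, grid=grid, budget=1, seed=0)
        assert len(log) == 1
        assert hp.to_dict() == log[0]["hp"]

    def test_learning_beats_not_learning(self, rng):
        # two-point grid: lr=0 cannot fit a signal-bearing problem
        trials = TestTraining().tiny_trials(rng, n=12)
        grid = self.one_point_grid(learning_rate=(0.0, 0.003), n_epochs=(25,))
        hp, log = tune_hyperparameters(trials, grid=grid, budget=2, seed=4)
        assert hp.learning_rate == 0.003
        assert len(log) == 2

    def test_empty_grid_rejected(self, rng):
        trials = TestTraining().tiny_trials(rng)
        with pytest.raises(ValueError):
            tune_hyperparameters(trials, grid={"learning_rate": ()}, budget=1)


class TestModelObjects:
    def test_fit_predict_summary_roundtrip(self, rng, tmp_path):
        trials = TestTraining().tiny_trials(rng, n=6)
        model = ForceLSTM([f for f, _ in trials], [y for _, y in trials], units=(4, 3))
        res = model.fit(HyperParams(n_epochs=3, batch_size=3), seed=9)
        pred = res.predict(trials[0][0])
        assert pred.shape == (12,) and np.all(pred >= 0)
        text = res.summary()
        assert "Stack LSTM" in text and "5 -> 4 -> 3 -> 1" in text

        save_params(tmp_path / "net.npz", res.params, res.hyperparams)
        loaded, meta = load_params(tmp_path / "net.npz")
        np.testing.assert_array_equal(loaded.layer2.W_u, res.params.layer2.W_u)
        np.testing.assert_allclose(network_forward(trials[0][0], loaded), pred)
        assert meta["hyperparams"]["n_epochs"] == 3
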