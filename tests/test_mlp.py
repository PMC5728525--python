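"""Perceptron construction, forward pass, backprop training, and evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mlpgrid as mg
from mlpgrid.mlp import (
    TrainingDivergence,
    _backprop_gradients,
    activation_derivative,
)


def _arch(nhl, af, n_in=3, n_out=6, row=0):
    return mg.ArchitectureSpec(1, row, tuple(nhl), tuple(af), n_in, n_out)


class TestActivation:
    def test_tansig_is_odd_and_zero_at_origin(self):
        assert mg.activation(1, 0.0) == 0.0
        x = np.linspace(-3, 3, 11)
        assert np.allclose(mg.activation(1, x), -mg.activation(1, -x))
        # equals the 2/(1+e^(-2x)) - 1 form
        assert np.allclose(mg.activation(1, x), 2.0 / (1.0 + np.exp(-2 * x)) - 1.0)

    def test_logsig_midpoint_and_range(self):
        assert mg.activation(2, 0.0) == 0.5
        x = np.linspace(-800, 800, 21)     # overflow-safe
        y = mg.activation(2, x)
        assert np.all((y >= 0) & (y <= 1)) and np.all(np.isfinite(y))

    def test_linear_is_identity(self):
        assert mg.activation(3, -4.2) == -4.2

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            mg.activation(4, 0.0)
        with pytest.raises(ValueError):
            activation_derivative(0, 0.0)


class TestBuildNetwork:
    def test_layer_shapes(self):
        net = mg.build_network(_arch([3], [1, 1]))
        assert [W.shape for W in net.weights] == [(3, 3), (6, 3)]
        assert [b.shape for b in net.biases] == [(3,), (6,)]

    def test_zero_init_sets_everything_to_zero(self):
        net = mg.build_network(_arch([4, 2], [1, 2, 3]), "zero", seed=123)
        assert all(np.all(W == 0) for W in net.weights)
        assert all(np.all(b == 0) for b in net.biases)

    def test_small_random_bounds_and_determinism(self):
        a = _arch([5], [1, 3], row=17)
        n1 = mg.build_network(a, "small-random", seed=9)
        n2 = mg.build_network(a, "small-random", seed=9)
        for W1, W2 in zip(n1.weights, n2.weights):
            assert np.array_equal(W1, W2)
            assert np.all(np.abs(W1) <= 0.5)
        n3 = mg.build_network(_arch([5], [1, 3], row=18), "small-random", seed=9)
        assert not np.array_equal(n1.weights[0], n3.weights[0])

    def test_json_round_trip(self):
        net = mg.build_network(_arch([4], [2, 3]), seed=1)
        back = mg.TrainedNetwork.from_dict(net.to_dict())
        for W1, W2 in zip(net.weights, back.weights):
            assert np.array_equal(W1, W2)
        assert back.activations == net.activations


class TestForward:
    def test_zero_network_linear_output_is_zero(self):
        net = mg.build_network(_arch([3], [3, 3]), "zero")
        out = mg.forward(net, np.ones((4, 3)))
        assert np.array_equal(out, np.zeros((4, 6)))

    def test_identity_single_linear_layer(self):
        net = mg.TrainedNetwork((3, 3), (3,), [np.eye(3)], [np.zeros(3)])
        x = np.random.default_rng(0).normal(size=(5, 3))
        assert np.allclose(mg.forward(net, x), x)

    def test_batch_shape_contract(self):
        net = mg.build_network(_arch([4, 4], [1, 2, 3]), seed=0)
        assert mg.forward(net, np.zeros((5, 3))).shape == (5, 6)
        assert mg.forward(net, np.zeros(3)).shape == (6,)

    def test_width_mismatch_rejected(self):
        net = mg.build_network(_arch([3], [1, 1]), seed=0)
        with pytest.raises(ValueError):
            mg.forward(net, np.zeros((2, 4)))


class TestSSE:
    def test_examples(self):
        t = np.array([[1.0, 2.0]])
        assert mg.sse(t, t) == 0.0
        assert mg.sse(t, np.zeros((1, 2))) == 5.0

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        t, y = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        base = mg.sse(t, y)
        assert np.isclose(mg.sse(t, t + 2 * (y - t)), 4 * base)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mg.sse(np.zeros((2, 2)), np.zeros((2, 3)))


class TestGradients:
    @pytest.mark.parametrize("af", [(1, 1), (2, 3), (3, 2), (1, 2, 3), (2, 3, 1, 2)])
    def test_backprop_matches_central_differences(self, af):
        rng = np.random.default_rng(hash(af) % 2**31)
        nhl = tuple(int(rng.integers(2, 5)) for _ in range(len(af) - 1))
        net = mg.build_network(_arch(nhl, af, n_out=2), seed=3)
        X = rng.uniform(-1, 1, (6, 3))
        T = rng.uniform(-1, 1, (6, 2))
        gW, gb, _ = _backprop_gradients(net, X, T)
        n, h = X.shape[0], 1e-6

        def fd(param, idx):
            param[idx] += h
            _, _, up = _backprop_gradients(net, X, T)
            param[idx] -= 2 * h
            _, _, dn = _backprop_gradients(net, X, T)
            param[idx] += h
            return (up - dn) / (2 * h) / n

        for l in range(net.n_weight_layers):
            for idx in np.ndindex(net.weights[l].shape):
                ref = fd(net.weights[l], idx)
                assert abs(gW[l][idx] - ref) <= 1e-5 * max(1.0, abs(ref))
            for (idx,) in np.ndindex(net.biases[l].shape):
                ref = fd(net.biases[l], (idx,))
                assert abs(gb[l][idx] - ref) <= 1e-5 * max(1.0, abs(ref))


class TestTrain:
    def test_zero_epochs_leaves_parameters_unchanged(self, linear_dataset):
        net = mg.build_network(_arch([3], [1, 1]), seed=0)
        cfg = mg.TrainConfig(seed=0, max_epochs=0, normalize=False)
        fitted, rec = mg.train(net, linear_dataset, cfg)
        assert rec.elapsed_epochs == 0 and len(rec.sse_trace) == 0
        for W1, W2 in zip(net.weights, fitted.weights):
            assert np.array_equal(W1, W2)

    def test_input_network_not_mutated(self, linear_dataset):
        net = mg.build_network(_arch([3], [3, 3]), seed=0)
        before = [W.copy() for W in net.weights]
        mg.train(net, linear_dataset, mg.TrainConfig(seed=0, max_epochs=20))
        for W0, W1 in zip(before, net.weights):
            assert np.array_equal(W0, W1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_learning_rate_gives_monotone_trace(self, seed):
        rng = np.random.default_rng(seed)
        data = mg.Dataset(rng.uniform(-1, 1, (30, 3)), rng.uniform(-1, 1, (30, 6)))
        net = mg.build_network(_arch([4], [1, 2], row=seed), seed=seed)
        cfg = mg.TrainConfig(
            seed=seed, max_epochs=200, learning_rate=1e-3, momentum=0.0,
            normalize=False, sse_tolerance=0.0,
        )
        _, rec = mg.train(net, data, cfg)
        assert np.all(np.diff(rec.sse_trace) <= 1e-12)

    def test_linear_limit_reaches_least_squares_optimum(self, linear_dataset):
        # independent closed-form oracle: ordinary least squares with intercept
        X, Y = linear_dataset.inputs, linear_dataset.targets
        Xa = np.hstack([X, np.ones((len(X), 1))])
        beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
        ls_sse = mg.sse(Y, Xa @ beta)
        net = mg.build_network(_arch([3], [3, 3]), seed=1)
        cfg = mg.TrainConfig(
            seed=1, max_epochs=4000, normalize=False, split_fraction=1.0,
            sse_tolerance=0.0,
        )
        fitted, rec = mg.train(net, linear_dataset, cfg)
        assert rec.sse_trace[-1] <= ls_sse + 1e-6

    def test_divergence_raises_with_epoch(self, linear_dataset):
        net = mg.build_network(_arch([3], [3, 3]), seed=0)
        cfg = mg.TrainConfig(
            seed=0, max_epochs=500, learning_rate=50.0, normalize=False
        )
        with pytest.raises(TrainingDivergence) as err:
            mg.train(net, linear_dataset, cfg)
        assert err.value.epoch >= 0

    def test_zero_init_keeps_hidden_units_identical(self):
        rng = np.random.default_rng(5)
        data = mg.Dataset(rng.uniform(-1, 1, (20, 3)), rng.uniform(-1, 1, (20, 6)))
        net = mg.build_network(_arch([4], [1, 3]), "zero")
        cfg = mg.TrainConfig(seed=0, max_epochs=50, init_scheme="zero", normalize=False)
        fitted, _ = mg.train(net, data, cfg)
        W = fitted.weights[0]
        assert np.allclose(W, W[0])        # every hidden unit has the same row

    def test_normalization_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(5, 9, (40, 3))
        Y = rng.uniform(100, 200, (40, 6))
        data = mg.Dataset(X, Y)
        net = mg.build_network(_arch([4], [1, 3]), seed=2)
        fitted, _ = mg.train(net, data, mg.TrainConfig(seed=2, max_epochs=30))
        # manual pipeline: normalise, run the core stack, denormalise
        lo, hi = fitted.input_bounds
        z = 2 * (X - lo) / (hi - lo) - 1
        for W, b, code in zip(fitted.weights, fitted.biases, fitted.activations):
            z = mg.activation(code, z @ W.T + b)
        tlo, thi = fitted.target_bounds
        manual = (z + 1) / 2 * (thi - tlo) + tlo
        assert np.allclose(mg.forward(fitted, X), manual, atol=1e-12)


class TestEvaluateArchitecture:
    def test_deterministic_given_seed(self, milk_data, fast_cfg):
        a = _arch([6], [1, 2], row=3)
        r1 = mg.evaluate_architecture(a, milk_data, fast_cfg)
        r2 = mg.evaluate_architecture(a, milk_data, fast_cfg)
        assert r1.sse == r2.sse and r1.seed == r2.seed

    def test_split_depends_only_on_seed(self):
        cfg = mg.TrainConfig(seed=4)
        tr1, ev1 = mg.split_indices(100, cfg)
        tr2, ev2 = mg.split_indices(100, cfg)
        assert np.array_equal(tr1, tr2) and np.array_equal(ev1, ev2)
        assert len(tr1) == 70 and len(ev1) == 30
        assert sorted(np.concatenate([tr1, ev1])) == list(range(100))

    def test_perfect_fit_on_noiseless_linear_planted_data(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (60, 3))
        A = rng.uniform(-0.5, 0.5, (6, 3))
        data = mg.Dataset(X, X @ A.T)
        cfg = mg.TrainConfig(
            seed=2, max_epochs=3000, normalize=False, sse_tolerance=0.0
        )
        res = mg.evaluate_architecture(_arch([3], [3, 3]), data, cfg)
        assert res.sse == pytest.approx(0.0, abs=1e-6)

    def test_divergence_recorded_not_raised(self, milk_data):
        cfg = mg.TrainConfig(seed=0, max_epochs=200, learning_rate=100.0)
        res = mg.evaluate_architecture(_arch([9], [3, 3], row=1), milk_data, cfg)
        assert res.failed and np.isnan(res.sse)

    def test_planted_architecture_beats_minimal_linear_net(self):
        planted = _arch([6], [1, 1], n_in=3, n_out=6, row=4)
        data, _ = mg.generate_planted(planted, n_samples=150, seed=6, noise_sd=0.02)
        cfg = mg.TrainConfig(seed=6, max_epochs=300)
        at_truth = mg.evaluate_architecture(planted, data, cfg)
        tiny = _arch([1], [3, 3], n_in=3, n_out=6, row=0)
        at_tiny = mg.evaluate_architecture(tiny, data, cfg)
        assert at_truth.sse <= at_tiny.sse


class TestTrainConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"learning_rate": 0.0},
            {"momentum": -0.1},
            {"split_fraction": 0.0},
            {"split_fraction": 1.5},
            {"init_scheme": "bogus"},
            {"optimizer": "adam"},
            {"eval_on": "test"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mg.TrainConfig(**kwargs)

    def test_full_split_forces_training_eval(self):
        cfg = mg.TrainConfig(split_fraction=1.0)
        assert cfg.eval_on == "training"
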