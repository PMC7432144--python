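import numpy as np
import pytest

from hazelnet.neuralnet import (
    MLPModel,
    TrainConfig,
    TrainingDivergedError,
    _loss_and_grads,
    evaluate_model,
    forward,
    scale_inputs,
    train,
    unscale_target,
)


def toy_model(n_hidden=1, **overrides):
    fields = dict(
        hidden_weights=np.zeros((n_hidden, 4)),
        hidden_biases=np.zeros(n_hidden),
        output_weights=np.zeros(n_hidden),
        output_bias=0.0,
        input_min=np.zeros(4),
        input_max=np.full(4, 2.0),
        target_min=0.0,
        target_max=10.0,
    )
    fields.update(overrides)
    return MLPModel(**fields)


class TestForward:
    def test_zero_weight_network_predicts_constant(self):
        model = toy_model(n_hidden=3, output_bias=0.2)
        pred = forward(model, np.ones((5, 4)))
        # scaled output 0.2 maps to 0 + (0.2 + 1)/2 * 10
        np.testing.assert_allclose(pred, np.full(5, 6.0))

    def test_single_neuron_hand_evaluation(self):
        model = toy_model(
            hidden_weights=np.array([[1.0, 0, 0, 0]]),
            output_weights=np.array([1.0]),
            target_min=-1.0,
            target_max=1.0,
        )
        x = np.array([[1.5, 1.0, 1.0, 1.0]])  # first input scales to 0.5
        assert forward(model, x)[0] == pytest.approx(np.tanh(0.5))

    def test_scaling_round_trip(self, rng):
        model = toy_model()
        X = rng.uniform(0, 2, size=(50, 4))
        ys = rng.uniform(-1, 1, size=50)
        back = (scale_inputs(model, X) + 1) / 2 * (model.input_max - model.input_min)
        np.testing.assert_allclose(back + model.input_min, X, atol=1e-12)
        np.testing.assert_allclose(
            2 * (unscale_target(model, ys) - model.target_min)
            / (model.target_max - model.target_min) - 1,
            ys, atol=1e-12,
        )

    def test_extrapolation_warns_but_predicts(self):
        model = toy_model()
        with pytest.warns(UserWarning, match="extrapolation"):
            forward(model, np.full((1, 4), 5.0))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            forward(toy_model(), np.ones((3, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        n, h = 12, 3
        Xs = rng.uniform(-1, 1, size=(n, 4))
        ys = rng.uniform(-1, 1, size=n)
        W = rng.normal(scale=0.5, size=(h, 4))
        b = rng.normal(scale=0.5, size=h)
        v = rng.normal(scale=0.5, size=h)
        c = 0.3
        _, dW, db, dv, dc = _loss_and_grads(W, b, v, c, Xs, ys)
        eps = 1e-6

        def loss(W, b, v, c):
            return _loss_and_grads(W, b, v, c, Xs, ys)[0]

        for arr, grad in ((W, dW), (b, db), (v, dv)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + eps
                up = loss(W, b, v, c)
                arr[i] = orig - eps
                down = loss(W, b, v, c)
                arr[i] = orig
                fd = (up - down) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        fd_c = (loss(W, b, v, c + eps) - loss(W, b, v, c - eps)) / (2 * eps)
        assert dc == pytest.approx(fd_c, rel=1e-5, abs=1e-8)


class TestTraining:
    def test_noiseless_linear_target_learned(self, rng):
        X = rng.uniform(0, 10, size=(120, 4))
        y = 1.0 + X @ [0.5, -0.3, 0.2, 0.7]
        model = train(X, y, n_hidden=3, seed=1)
        assert evaluate_model(model, X, y).r2 >= 0.999

    def test_same_seed_gives_identical_models(self, rng):
        X = rng.uniform(0, 10, size=(60, 4))
        y = X @ [1.0, 0.5, -0.2, 0.3] + rng.normal(size=60)
        a = train(X, y, n_hidden=4, seed=3)
        b = train(X, y, n_hidden=4, seed=3)
        np.testing.assert_array_equal(a.hidden_weights, b.hidden_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert a.output_bias == b.output_bias

    def test_divergence_raises_with_advice(self, rng):
        X = rng.uniform(0, 10, size=(40, 4))
        y = X.sum(axis=1)
        with pytest.raises(TrainingDivergedError, match="learning rate"):
            train(X, y, n_hidden=4, seed=0,
                  config=TrainConfig(learning_rate=1e9, max_error_ratio=1e12))

    def test_metrics_invariant_to_row_order(self, rng, default_xy):
        X, table = default_xy
        y = table.dw.to_numpy()
        model = train(X, y, n_hidden=4, seed=2,
                      config=TrainConfig(max_epochs=500))
        perm = rng.permutation(len(y))
        before = evaluate_model(model, X, y)
        after = evaluate_model(model, X[perm], y[perm])
        assert before.rmse == pytest.approx(after.rmse)
        assert before.r2 == pytest.approx(after.r2)

    def test_shuffled_targets_are_unlearnable(self, rng, default_xy):
        X, table = default_xy
        y = rng.permutation(table.total.to_numpy())
        model = train(X, y, n_hidden=4, seed=5,
                      config=TrainConfig(max_epochs=800))
        assert evaluate_model(model, X, y).r2 < 0.2

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            train(np.ones((5, 4)), np.ones(5), n_hidden=2)

    def test_serialization_round_trip(self, rng):
        X = rng.uniform(0, 10, size=(60, 4))
        y = X @ [1.0, 0.5, -0.2, 0.3]
        model = train(X, y, n_hidden=3, seed=9,
                      config=TrainConfig(max_epochs=300))
        clone = MLPModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(forward(clone, X), forward(model, X))
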