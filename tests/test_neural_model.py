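import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kldnet import (
    FocalLossConfig,
    ModelParameters,
    NetworkConfig,
    cross_entropy_loss,
    focal_loss,
    forward,
    load_checkpoint,
    loss_and_gradients,
    predict,
    save_checkpoint,
    train,
)

from conftest import make_labelled


def random_params(rng, d=4, h1=3, h2=2):
    return ModelParameters(
        rng.normal(0, 0.7, (d, h1)),
        rng.normal(0, 0.3, h1),
        rng.normal(0, 0.7, (h1, h2)),
        rng.normal(0, 0.3, h2),
        rng.normal(0, 0.7, h2),
        rng.normal(0, 0.3),
    )


def finite_difference_grads(X, y, p, loss, loss_cfg, strict=False, h=1e-6):
    """Central-difference oracle for the loss gradient, parameter by parameter."""

    def eval_at(name, flat_values, shape):
        q = dataclasses.replace(p)
        if name == "b3":
            q.b3 = float(flat_values[0])
        else:
            setattr(q, name, flat_values.reshape(shape))
        l, _ = loss_and_gradients(X, y, q, loss, loss_cfg, strict)
        return l

    grads = {}
    for name in ("W1", "b1", "W2", "b2", "w3", "b3"):
        base = np.atleast_1d(np.array(getattr(p, name), dtype=float))
        g = np.zeros(base.size)
        flat = base.ravel()
        for i in range(flat.size):
            up, down = flat.copy(), flat.copy()
            up[i] += h
            down[i] -= h
            g[i] = (eval_at(name, up, base.shape) - eval_at(name, down, base.shape)) / (2 * h)
        grads[name] = float(g[0]) if name == "b3" else g.reshape(base.shape)
    return grads


class TestForward:
    def test_zero_parameters_give_half(self):
        p = ModelParameters(
            np.zeros((3, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2),
            np.zeros(2), 0.0,
        )
        out = forward(np.random.default_rng(0).normal(size=(5, 3)), p)
        np.testing.assert_allclose(out, 0.5)

    def test_outputs_in_open_unit_interval(self):
        rng = np.random.default_rng(1)
        p = random_params(rng)
        out = forward(rng.normal(0, 10, (50, 4)), p)
        assert np.all(out > 0) and np.all(out < 1)

    def test_hand_evaluated_chain(self):
        # 1 feature, both hidden widths 1, all weights 1, biases 0, x=2:
        # relu(relu(2*1)*1)*1 = 2 -> sigmoid(2)
        p = ModelParameters(
            np.ones((1, 1)), np.zeros(1), np.ones((1, 1)), np.zeros(1),
            np.ones(1), 0.0,
        )
        out = forward(np.array([[2.0]]), p)
        assert out[0] == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        assert out[0] == pytest.approx(0.8808, abs=5e-5)

    def test_shape_mismatch_rejected(self):
        p = random_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            forward(np.zeros((2, 5)), p)


class TestLosses:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy_loss(np.array([1.0]), np.array([1 - 1e-7])) <= 1.2e-7

    def test_cross_entropy_hand_values(self):
        assert cross_entropy_loss(
            np.array([1.0, 0.0]), np.array([0.5, 0.5])
        ) == pytest.approx(np.log(2), abs=1e-12)
        assert cross_entropy_loss(np.array([0.0]), np.array([0.9])) == pytest.approx(
            -np.log(0.1), abs=1e-9
        )

    def test_focal_hand_values(self):
        cfg = FocalLossConfig(alpha=0.25, gamma=2.0, variant="as_printed")
        assert focal_loss(np.array([1.0]), np.array([0.9]), cfg) == pytest.approx(
            0.25 * 0.01 * -np.log(0.9), rel=1e-9
        )
        # printed form: no alpha on the negative-class term
        assert focal_loss(np.array([0.0]), np.array([0.9]), cfg) == pytest.approx(
            0.81 * -np.log(0.1), rel=1e-9
        )

    def test_standard_variant_weights_negative_term(self):
        y, yhat = np.array([0.0]), np.array([0.9])
        printed = focal_loss(y, yhat, FocalLossConfig(0.25, 2.0, "as_printed"))
        standard = focal_loss(y, yhat, FocalLossConfig(0.25, 2.0, "standard"))
        assert standard == pytest.approx(0.75 * printed, rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(1, 40), st.integers(0, 2**31 - 1))
    def test_focal_gamma_zero_alpha_one_reduces_to_cross_entropy(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n).astype(float)
        yhat = rng.uniform(1e-6, 1 - 1e-6, n)
        cfg = FocalLossConfig(alpha=1.0, gamma=0.0, variant="as_printed")
        assert focal_loss(y, yhat, cfg) == pytest.approx(
            cross_entropy_loss(y, yhat), abs=1e-12
        )

    def test_per_sample_downweighting_of_easy_positives(self):
        """For a correctly classified positive the focal term is strictly
        below alpha x its cross-entropy term."""
        cfg = FocalLossConfig(alpha=0.25, gamma=2.0)
        for p in np.linspace(0.51, 0.999, 20):
            focal_term = focal_loss(np.array([1.0]), np.array([p]), cfg)
            ce_term = cross_entropy_loss(np.array([1.0]), np.array([p]))
            assert focal_term < cfg.alpha * ce_term

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([1.0, 0.0]), np.array([0.5]))


class TestGradients:
    @pytest.mark.parametrize("loss", ["cross_entropy", "focal"])
    def test_backprop_matches_finite_differences(self, loss):
        rng = np.random.default_rng(2024)
        cfg = FocalLossConfig(alpha=0.25, gamma=2.0)
        for _ in range(3):
            p = random_params(rng)
            X = rng.normal(0, 1, (8, 4))
            y = rng.integers(0, 2, 8).astype(float)
            _, an = loss_and_gradients(X, y, p, loss, cfg)
            fd = finite_difference_grads(X, y, p, loss, cfg)
            for name in an:
                a = np.ravel(an[name]).astype(float)
                f = np.ravel(fd[name]).astype(float)
                denom = max(np.linalg.norm(f), 1e-8)
                assert np.linalg.norm(a - f) / denom < 1e-5, name

    def test_strict_mode_gradients(self):
        rng = np.random.default_rng(7)
        p = ModelParameters(
            rng.normal(0, 0.7, (3, 4)), np.zeros(4),
            rng.normal(0, 0.7, (4, 1)), np.zeros(1), np.ones(1), 0.0,
        )
        X = rng.normal(0, 1, (6, 3))
        y = rng.integers(0, 2, 6).astype(float)
        _, an = loss_and_gradients(X, y, p, "focal", FocalLossConfig(), strict=True)
        fd = finite_difference_grads(X, y, p, "focal", FocalLossConfig(), strict=True)
        for name in ("W1", "W2"):
            denom = max(np.linalg.norm(np.ravel(fd[name])), 1e-8)
            err = np.linalg.norm(np.ravel(an[name]) - np.ravel(fd[name])) / denom
            assert err < 1e-5
        # the literal architecture trains no biases and no output layer
        assert np.all(an["b1"] == 0) and np.all(an["b2"] == 0)
        assert np.all(an["w3"] == 0) and an["b3"] == 0


class TestTraining:
    def net(self, **kw):
        base = dict(input_dim=2, hidden_sizes=(8, 4), seed=3, epochs=200,
                    batch_size=4, loss="focal", standardize="log2p1_zscore")
        base.update(kw)
        return NetworkConfig(**base)

    def test_separable_toy_reaches_perfect_training_accuracy(self, separable_toy):
        model = train(separable_toy, self.net())
        yhat = predict(model, separable_toy.matrix.values.T)
        assert np.all((yhat >= 0.5) == (separable_toy.y == 1))

    def test_training_reduces_loss(self, separable_toy):
        model = train(separable_toy, self.net(epochs=50))
        assert model.training_loss_trace[-1] <= model.training_loss_trace[0]
        assert np.all(np.isfinite(model.training_loss_trace))

    def test_seeded_determinism_bit_identical(self, separable_toy):
        m1 = train(separable_toy, self.net())
        m2 = train(separable_toy, self.net())
        np.testing.assert_array_equal(m1.training_loss_trace, m2.training_loss_trace)
        np.testing.assert_array_equal(m1.params.W1, m2.params.W1)
        np.testing.assert_array_equal(m1.params.w3, m2.params.w3)

    def test_different_seed_changes_parameters(self, separable_toy):
        m1 = train(separable_toy, self.net())
        m2 = train(separable_toy, self.net(seed=4))
        assert not np.array_equal(m1.params.W1, m2.params.W1)

    def test_predict_consistency_and_duplicates(self, separable_toy):
        model = train(separable_toy, self.net(epochs=20))
        X = separable_toy.matrix.values.T
        yhat = predict(model, X)
        dup = np.vstack([X[0], X[0]])
        out = predict(model, dup)
        assert out[0] == out[1]
        assert np.all((yhat > 0) & (yhat < 1))

    def test_single_class_rejected(self):
        ds = make_labelled(np.ones((2, 6)), np.array([1] * 6))
        with pytest.raises(ValueError):
            train(ds, self.net())

    def test_input_dim_mismatch_rejected(self, separable_toy):
        with pytest.raises(ValueError, match="input_dim"):
            train(separable_toy, self.net(input_dim=5))

    def test_strict_output_requires_unit_width(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_dim=2, hidden_sizes=(8, 4), strict_output=True)

    def test_strict_mode_trains(self, separable_toy):
        cfg = self.net(hidden_sizes=(8, 1), strict_output=True)
        model = train(separable_toy, cfg)
        assert np.all(model.params.b1 == 0) and np.all(model.params.b2 == 0)
        yhat = predict(model, separable_toy.matrix.values.T)
        assert np.all((yhat > 0) & (yhat < 1))

    def test_checkpoint_round_trip(self, separable_toy, tmp_path):
        model = train(separable_toy, self.net(epochs=20))
        path = save_checkpoint(model, tmp_path / "model.json")
        loaded = load_checkpoint(path)
        X = separable_toy.matrix.values.T
        np.testing.assert_array_equal(predict(model, X), predict(loaded, X))
        assert loaded.config == model.config
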