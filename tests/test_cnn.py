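import numpy as np
import pytest

from cardiostack.cnn import CnnConfig, TINY_CHANNELS, build_model, predict_record, train_classifier
from cardiostack.cnn.layers import Adam, BatchNorm2d, Conv2d, GlobalAvgPool, Linear, MaxPool2, ReLU, cross_entropy, softmax

MICRO = CnnConfig(input_shape=(16, 16), channels=TINY_CHANNELS, epochs=2, seed=0)


class TestArchitecture:
    def test_softmax_head_normalized(self, rng):
        model = build_model(MICRO)
        out = model.forward(rng.standard_normal((4, 16, 16)))
        assert out.shape == (4, 2)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-6)
        assert (out >= 0).all()

    def test_audit_reports_skeleton(self):
        audit = build_model(MICRO).audit()
        assert audit["n_conv"] == 10
        assert audit["bn_blocks"] == [1, 10]
        assert audit["pool_blocks"] == [4, 6, 9, 10]
        assert audit["output_dim"] == 2

    def test_downsampling_factor_is_16_per_axis(self, rng):
        # trace the feature map through the block list up to the global pool
        model = build_model(CnnConfig(input_shape=(32, 32), channels=TINY_CHANNELS, seed=0))
        x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
        for block in model.blocks:
            for layer in block:
                x = layer.forward(x, train=False)
        assert x.shape[2:] == (2, 2)  # 32 / 2**4

    def test_same_seed_same_outputs(self, rng):
        x = rng.standard_normal((3, 16, 16))
        a = build_model(MICRO).forward(x)
        b = build_model(MICRO).forward(x)
        assert np.array_equal(a, b)

    def test_wrong_input_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            build_model(MICRO).forward(rng.standard_normal((2, 20, 20)))

    def test_wrong_block_count_rejected(self):
        with pytest.raises(ValueError, match="10"):
            CnnConfig(input_shape=(16, 16), channels=(4, 4, 4))

    def test_state_round_trip(self, tmp_path, rng):
        model = build_model(MICRO)
        x = rng.standard_normal((2, 16, 16))
        ref = model.forward(x)
        model.save(tmp_path / "model")
        from cardiostack.cnn.model import Cnn

        clone = Cnn.load(tmp_path / "model")
        assert np.allclose(clone.forward(x), ref, atol=1e-7)


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        up = f()
        x[idx] = orig - eps
        down = f()
        x[idx] = orig
        g[idx] = (up - down) / (2 * eps)
    return g


class TestBackprop:
    """Gradient checks of each layer against central differences."""

    @pytest.mark.parametrize("layer_name", ["conv", "bn", "pool", "linear"])
    def test_layer_gradients(self, layer_name, rng):
        r = np.random.default_rng(7)
        if layer_name == "conv":
            layer = Conv2d(2, 3, 3, r)
            x = r.standard_normal((2, 2, 5, 5)).astype(np.float32)
        elif layer_name == "bn":
            layer = BatchNorm2d(3)
            x = r.standard_normal((4, 3, 4, 4)).astype(np.float32)
        elif layer_name == "pool":
            layer = MaxPool2()
            x = r.standard_normal((2, 2, 6, 6)).astype(np.float32)
        else:
            layer = Linear(6, 4, r)
            x = r.standard_normal((3, 6)).astype(np.float32)
        w = r.standard_normal(layer.forward(x, train=True).shape).astype(np.float32)

        def loss():
            return float((layer.forward(x, train=True) * w).sum())

        loss()  # populate caches
        dx = layer.backward(w)
        assert np.allclose(dx, _numeric_grad(loss, x), atol=2e-2)

    def test_cross_entropy_gradient_soft_labels(self, rng):
        logits = rng.standard_normal((4, 2)).astype(np.float64)
        soft = np.array([[0.7, 0.3], [0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])

        def loss():
            return cross_entropy(softmax(logits), soft)[0]

        _, d = cross_entropy(softmax(logits), soft)
        assert np.allclose(d, _numeric_grad(loss, logits, eps=1e-5), atol=1e-6)


def _separable_images(n, rng, shape=(16, 16)):
    y = rng.integers(0, 2, n)
    x = rng.standard_normal((n, *shape)).astype(np.float32) * 0.3
    x[y == 1, 4:12, 4:12] += 1.0
    return x, y


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        x, y = _separable_images(96, rng)
        cfg = CnnConfig(input_shape=(16, 16), channels=TINY_CHANNELS, epochs=10, seed=1)
        result = train_classifier(x, y, cfg)
        losses = [h["train_loss"] for h in result.history]
        # monotone trend over 5-epoch windows
        assert np.mean(losses[5:]) < np.mean(losses[:5])

    def test_training_reproducible(self, rng):
        x, y = _separable_images(48, rng)
        cfg = CnnConfig(input_shape=(16, 16), channels=TINY_CHANNELS, epochs=2, seed=5)
        a = train_classifier(x, y, cfg)
        b = train_classifier(x, y, cfg)
        assert a.history == b.history
        assert np.array_equal(a.model.predict_proba(x), b.model.predict_proba(x))

    def test_single_class_training_rejected(self, rng):
        x, _ = _separable_images(10, rng)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(x, np.zeros(10, dtype=int), MICRO)

    def test_adam_updates_parameters(self, rng):
        model = build_model(MICRO)
        before = [p.copy() for p in model.state()]
        opt = model.make_optimizer()
        x, y = _separable_images(8, rng)
        model.train_step(x[:, None], np.eye(2, dtype=np.float32)[y], opt)
        after = model.state()
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))


class TestPredictRecord:
    class _Stub:
        def __init__(self, probs):
            self._p = np.asarray(probs)

        def predict_proba(self, x):
            return self._p[: len(x)]

    def test_single_segment_passthrough(self):
        assert predict_record(self._Stub([0.73]), np.zeros((1, 4, 4))) == pytest.approx(0.73)

    def test_mean_aggregation(self):
        assert predict_record(self._Stub([0.2, 0.4, 0.9]), np.zeros((3, 4, 4))) == pytest.approx(0.5)

    def test_max_aggregation_available(self):
        assert predict_record(self._Stub([0.2, 0.9]), np.zeros((2, 4, 4)), aggregate="max") == pytest.approx(0.9)

    def test_probability_in_unit_interval(self, rng):
        model = build_model(MICRO)
        p = predict_record(model, rng.standard_normal((5, 16, 16)))
        assert 0.0 <= p <= 1.0

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="no segments"):
            predict_record(self._Stub([]), np.zeros((0, 4, 4)))
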