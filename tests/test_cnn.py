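"""Network engine: architecture audit, gradients, training behaviour."""

import numpy as np
import pytest

from readeog import DyslexiaNetClassifier, build_model, count_learnables, dyslexianet
from readeog.cnn import LayerSpec, ModelSpec, softmax_cross_entropy

# Per-layer learnable counts implied by the published layer table.
TABLE_COUNTS = {
    "conv_1": 784, "batchnorm_1": 32,
    "conv_2": 8224, "batchnorm_2": 64,
    "conv_3": 32832, "batchnorm_3": 128,
    "conv_4": 65600, "batchnorm_4": 128,
    "fc": 1154,
}


class TestArchitecture:
    @pytest.mark.parametrize("layer,expected", sorted(TABLE_COUNTS.items()))
    def test_learnable_counts(self, layer, expected):
        assert count_learnables(dyslexianet(), layer) == expected

    def test_activation_free_layers_have_zero_learnables(self):
        spec = dyslexianet()
        for name in ("relu_1", "maxpool_1", "dropout", "imageinput", "softmax"):
            assert count_learnables(spec, name) == 0

    def test_unknown_layer_rejected(self):
        with pytest.raises(KeyError):
            count_learnables(dyslexianet(), "conv_9")

    def test_fc_input_dimension_576(self):
        """Pooling schedule 28→7→3 leaves a 3x3x64 map: fc input 576."""
        model = build_model(dyslexianet(), seed=0)
        fc = model.layers[-1]
        assert fc.params["W"].shape == (576, 2)

    def test_total_learnables(self):
        model = build_model(dyslexianet(), seed=0)
        assert sum(model.learnables.values()) == sum(TABLE_COUNTS.values())

    def test_shape_inconsistent_spec_names_layer(self):
        bad = ModelSpec(layers=(
            LayerSpec("imageinput", "input"),
            LayerSpec("bigpool", "maxpool", filter_size=(40, 40), stride=40),
            LayerSpec("fc", "fully_connected", units=2),
            LayerSpec("softmax", "softmax"),
        ))
        with pytest.raises(ValueError, match="bigpool"):
            build_model(bad, seed=0)

    def test_wrong_output_width_rejected(self):
        bad = ModelSpec(layers=(
            LayerSpec("imageinput", "input"),
            LayerSpec("fc", "fully_connected", units=5),
            LayerSpec("softmax", "softmax"),
        ))
        with pytest.raises(ValueError, match="expected 2"):
            build_model(bad, seed=0)


class TestForwardBackward:
    def test_untrained_probabilities_sum_to_one(self):
        model = build_model(dyslexianet(), seed=1)
        x = np.random.default_rng(0).normal(size=(5, 28, 28, 3))
        p = model.predict_proba(x)
        assert p.shape == (5, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop vs central differences on a miniature net
        containing every layer kind (float64, eps=1e-6)."""
        L = LayerSpec
        spec = ModelSpec(layers=(
            L("in", "input"),
            L("c1", "conv", filter_size=(3, 3), n_filters=2),
            L("b1", "batchnorm"),
            L("r1", "relu"),
            L("p1", "maxpool", filter_size=(2, 2), stride=2),
            L("fc", "fully_connected", units=2),
            L("sm", "softmax"),
        ), input_shape=(6, 6, 1), n_classes=2)
        model = build_model(spec, seed=0)
        for layer, key in model.parameters():
            layer.params[key] = layer.params[key].astype(np.float64)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 6, 6, 1))
        y = np.array([0, 1, 0, 1])
        _, dlogits = softmax_cross_entropy(model.forward(x, train=True), y)
        model.backward(dlogits.astype(np.float64))
        for layer, key in model.parameters():
            grad = np.asarray(layer.grads[key])
            p = layer.params[key].reshape(-1)
            g = grad.reshape(-1)
            for i in range(0, p.size, max(1, p.size // 6)):
                eps, old = 1e-6, p[i]
                p[i] = old + eps
                lp = softmax_cross_entropy(model.forward(x, train=True), y)[0]
                p[i] = old - eps
                lm = softmax_cross_entropy(model.forward(x, train=True), y)[0]
                p[i] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[i], rel=1e-4, abs=1e-7)


class TestClassifierEstimator:
    def test_sklearn_params_roundtrip(self):
        clf = DyslexiaNetClassifier(epochs=3, random_state=7)
        params = clf.get_params()
        assert params["epochs"] == 3
        clone = DyslexiaNetClassifier(**params)
        assert clone.get_params() == params

    def test_fit_reduces_loss_and_predicts(self, tone_images):
        images, labels = tone_images
        clf = DyslexiaNetClassifier(epochs=6, batch_size=16, random_state=0)
        clf.fit(images, labels)
        assert clf.loss_history_[-1] < clf.loss_history_[0]
        assert set(clf.classes_) == set(labels)
        pred = clf.predict(images)
        assert (pred == labels).mean() > 0.9  # training-set separability

    def test_deterministic_given_random_state(self, tone_images):
        """Same seed ⇒ same initialisation, dropout and shuffling; outputs
        agree to float32 accumulation order (BLAS threading)."""
        images, labels = tone_images
        idx = np.r_[0:20, 50:70]  # both classes
        a = DyslexiaNetClassifier(epochs=2, batch_size=16, random_state=3)
        b = DyslexiaNetClassifier(epochs=2, batch_size=16, random_state=3)
        pa = a.fit(images[idx], labels[idx]).predict_proba(images[idx])
        pb = b.fit(images[idx], labels[idx]).predict_proba(images[idx])
        np.testing.assert_allclose(pa, pb, rtol=1e-3, atol=1e-4)
        assert np.array_equal(np.argmax(pa, 1), np.argmax(pb, 1))

    def test_wrong_shape_rejected(self):
        clf = DyslexiaNetClassifier()
        with pytest.raises(ValueError, match="shape"):
            clf.fit(np.zeros((4, 10, 10, 3)), ["a", "b", "a", "b"])
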