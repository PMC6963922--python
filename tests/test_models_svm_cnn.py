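import numpy as np
import pytest

from hsifruit.errors import ArchitectureError, StratificationError
from hsifruit.models import CNNSpec, SVMSpec, cnn_build, cnn_shape_arithmetic, svm_grid_search


def _blobs(rng, n_per_class=15, n_vars=6, sep=8.0, sd=0.4):
    centers = sep * np.eye(3, n_vars)
    X = np.vstack(
        [centers[c] + sd * rng.standard_normal((n_per_class, n_vars)) for c in range(3)]
    )
    y = np.repeat(np.arange(3), n_per_class)
    return X, y


class TestSVMGridSearch:
    def test_wide_margin_data_reaches_full_cv_accuracy(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng, sep=20.0, sd=0.2)
        C, g, acc, model = svm_grid_search(X, y, SVMSpec(seed=0))
        assert acc == 1.0
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(1)
        X, y = _blobs(rng)
        spec = SVMSpec(c_grid=(10.0,), g_grid=(0.1,), seed=0)
        C, g, _, _ = svm_grid_search(X, y, spec)
        assert (C, g) == (10.0, 0.1)

    def test_duplicated_features_same_best_pair(self):
        rng = np.random.default_rng(2)
        X, y = _blobs(rng, sep=20.0, sd=0.2)
        a = svm_grid_search(X, y, SVMSpec(seed=0))[:2]
        b = svm_grid_search(np.hstack([X, X]), y, SVMSpec(seed=0))[:2]
        assert a == b

    def test_tiny_class_raises_stratification_error(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 3))
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2])  # class 2 has 2 < 5 samples
        with pytest.raises(StratificationError):
            svm_grid_search(X, y, SVMSpec(seed=0))

    def test_grid_is_seventeen_decades(self):
        spec = SVMSpec()
        assert len(spec.c_grid) == 17 and len(spec.g_grid) == 17
        assert spec.c_grid[0] == pytest.approx(1e-8)
        assert spec.c_grid[-1] == pytest.approx(1e8)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X, y = _blobs(rng, sep=3.0, sd=1.5)
        a = svm_grid_search(X, y, SVMSpec(seed=7))
        b = svm_grid_search(X, y, SVMSpec(seed=7))
        assert a[:3] == b[:3]


class TestCNNShapes:
    def test_full_spectrum_arithmetic(self):
        sh = cnn_shape_arithmetic(200)
        assert (sh["conv1"], sh["pool1"], sh["conv2"], sh["pool2"]) == (198, 99, 97, 48)
        assert sh["flatten"] == 1536

    def test_effective_wavelength_arithmetic(self):
        sh = cnn_shape_arithmetic(22)
        assert (sh["conv1"], sh["pool1"], sh["conv2"], sh["pool2"]) == (20, 10, 8, 4)
        assert sh["flatten"] == 128

    def test_too_short_input_raises_with_arithmetic(self):
        with pytest.raises(ArchitectureError, match="conv1"):
            cnn_build(CNNSpec(), input_length=10)

    def test_minimum_viable_length(self):
        net = cnn_build(CNNSpec(), input_length=11)
        assert net.shapes["flatten"] == 32


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    n_per = 30
    t = np.linspace(0.0, 1.0, 30)
    prototypes = [0.5 + 0.2 * np.sin(2 * np.pi * t + phi) for phi in (0.0, 2.0, 4.0)]
    X = np.vstack([p + 0.02 * rng.standard_normal((n_per, 30)) for p in prototypes])
    y = np.repeat(np.arange(3), n_per)
    perm = rng.permutation(90)
    X, y = X[perm], y[perm]
    return (X[:60], y[:60], X[60:], y[60:])


class TestCNNTraining:
    def test_reaches_95_pct_validation(self, separable):
        Xc, yc, Xv, yv = separable
        spec = CNNSpec(batch_size=16, epochs=50, seed=0)
        net = cnn_build(spec, input_length=30)
        net.train(Xc, yc, Xv, yv)
        assert max(net.history) >= 0.95
        assert np.mean(net.predict(Xv) == yv) >= 0.95

    def test_deterministic_under_seed(self, separable):
        Xc, yc, Xv, yv = separable
        preds = []
        for _ in range(2):
            net = cnn_build(CNNSpec(batch_size=16, epochs=10, seed=3), input_length=30)
            net.train(Xc, yc, Xv, yv)
            preds.append(net.predict(Xv))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_batch_size_clamped_with_warning(self, separable):
        Xc, yc, Xv, yv = separable
        net = cnn_build(CNNSpec(batch_size=400, epochs=2, seed=0), input_length=30)
        with pytest.warns(UserWarning, match="clamp"):
            net.train(Xc, yc, Xv, yv)

    def test_epoch_best_model_kept(self, separable):
        Xc, yc, Xv, yv = separable
        net = cnn_build(CNNSpec(batch_size=16, epochs=25, seed=1), input_length=30)
        net.train(Xc, yc, Xv, yv)
        final_acc = np.mean(net.predict(Xv) == yv)
        assert final_acc == pytest.approx(max(net.history))

    def test_probabilities_argmax_consistent(self, separable):
        Xc, yc, Xv, yv = separable
        net = cnn_build(CNNSpec(batch_size=16, epochs=5, seed=2), input_length=30)
        net.train(Xc, yc, Xv, yv)
        probs = net.predict_proba(Xv)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(np.argmax(probs, axis=1), net.predict(Xv))

    def test_gradient_check_small_net(self):
        # finite-difference check of the full backward pass on a tiny batch
        rng = np.random.default_rng(6)
        net = cnn_build(CNNSpec(seed=0), input_length=12)
        X = rng.standard_normal((4, 12))
        y = np.array([0, 1, 2, 1])
        onehot = np.eye(3)[y]

        def loss_at():
            logits, _ = net._forward(X, train=True)
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            return -np.mean(np.log(p[np.arange(4), y]))

        logits, cache = net._forward(X, train=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        grads = net._backward((p - onehot) / 4.0, cache)
        eps = 1e-6
        for key in ("Wd3", "Wc1", "Wd1"):
            W = net.params[key]
            flat_index = 3 % W.size
            idx = np.unravel_index(flat_index, W.shape)
            orig = W[idx]
            W[idx] = orig + eps
            up = loss_at()
            W[idx] = orig - eps
            down = loss_at()
            W[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7)
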