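"""Numpy CNN engine: gradients, layer semantics, fit contract."""

import dataclasses

import numpy as np
import pytest

from cecgkit import ConvNet1D, TrainConfig, build_spec
from cecgkit.arch import build_network
from cecgkit import nn
from cecgkit.errors import ConfigurationError


def _analytic_and_numeric_grads(net, x, y, n_probe=12):
    """Backprop gradients vs central differences on sampled entries."""
    def loss():
        return nn.softmax_cross_entropy(net.forward(x.copy(), train=True), y)[0]

    grad = nn.softmax_cross_entropy(net.forward(x.copy(), train=True), y)[1]
    for layer in reversed(net.layers):
        grad = layer.backward(grad)
        if grad is None:
            break
    worst = 0.0
    pick = np.random.default_rng(1)
    for p, g in zip(net.params, net.grads):
        for flat_idx in pick.choice(p.size, size=min(n_probe, p.size), replace=False):
            idx = np.unravel_index(flat_idx, p.shape)
            eps, orig = 1e-6, p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            worst = max(worst, abs(num - g[idx]) / max(1e-8, abs(num) + abs(g[idx])))
    return worst


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """End-to-end gradient check through conv/ReLU/BN/pool/dense."""
        spec = dataclasses.replace(build_spec(3, 16, 8, n_classes=3), dropout_rate=0.0)
        rng = np.random.default_rng(0)
        net = build_network(spec, rng, dtype=np.float64)
        x = rng.normal(size=(4, 16, 1))
        y = np.eye(3)[rng.integers(0, 3, 4)]
        assert _analytic_and_numeric_grads(net, x, y) < 1e-5


class TestLayers:
    def test_batchnorm_training_statistics(self, rng):
        bn = nn.BatchNorm(3, epsilon=1e-3)
        x = rng.normal(2.0, 4.0, size=(8, 20, 3)).astype(np.float32)
        out = bn.forward(x, train=True)
        assert np.allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-5)

    def test_batchnorm_inference_uses_running_stats(self, rng):
        bn = nn.BatchNorm(2)
        x = rng.normal(5.0, 1.0, size=(16, 10, 2)).astype(np.float32)
        for _ in range(200):
            bn.forward(x, train=True)
        out = bn.forward(x, train=False)
        # running stats converged to the batch stats, so inference ~ training
        assert np.allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-2)

    def test_maxpool_halves_and_routes_gradient_to_argmax(self):
        pool = nn.MaxPool()
        x = np.array([[[1.0], [3.0], [2.0], [0.5], [9.0]]])  # odd length: drop tail
        out = pool.forward(x, train=True)
        assert out[0, :, 0].tolist() == [3.0, 2.0]
        dx = pool.backward(np.array([[[10.0], [20.0]]]))
        assert dx[0, :, 0].tolist() == [0.0, 10.0, 20.0, 0.0, 0.0]

    def test_dropout_scales_and_is_identity_at_inference(self, rng):
        drop = nn.Dropout(0.5)
        drop.rng = rng
        x = np.ones((4, 1000))
        out = drop.forward(x, train=True)
        kept = out[out > 0]
        assert np.allclose(kept, 2.0)  # inverted dropout rescales by 1/keep
        assert 0.35 < (out > 0).mean() < 0.65
        assert np.array_equal(drop.forward(x, train=False), x)

    def test_softmax_cross_entropy_loss_value(self):
        logits = np.log(np.array([[0.7, 0.2, 0.1]]))
        onehot = np.array([[1.0, 0.0, 0.0]])
        loss, _, _ = nn.softmax_cross_entropy(logits, onehot)
        assert loss == pytest.approx(-np.log(0.7), rel=1e-6)


@pytest.fixture(scope="module")
def separable_segments():
    """Two trivially distinct waveform classes as z-scored 2-s segments."""
    rng = np.random.default_rng(7)
    t = np.arange(600) / 300.0
    X, y = [], []
    for _ in range(100):
        ecg_like = np.zeros(600)
        for c in (0.5, 1.5):
            ecg_like += np.exp(-0.5 * ((t - c) / 0.012) ** 2)
        ecg_like += rng.normal(0, 0.05, 600)
        noise = rng.normal(0, 1.0, 600)
        for sig, lab in ((ecg_like, "beat"), (noise, "noise")):
            z = (sig - sig.mean()) / sig.std()
            X.append(z)
            y.append(lab)
    return np.array(X, dtype=np.float32), np.array(y, dtype=object)


class TestFit:
    def test_separable_classes_reach_high_training_accuracy(self, separable_segments):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "noise"))
        res = model.fit(X, y, config=TrainConfig(learning_rate=3e-3, max_epochs=10,
                                                 early_stop_patience=10, seed=0))
        assert res.history[-1]["accuracy"] >= 0.95
        assert res.predict_proba(X).shape == (200, 2)
        assert np.allclose(res.predict_proba(X[:5]).sum(axis=1), 1.0, atol=1e-6)

    def test_identical_seed_gives_identical_history(self, separable_segments):
        X, y = separable_segments
        cfg = TrainConfig(max_epochs=2, seed=3)
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "noise"))
        h1 = model.fit(X, y, config=cfg).history
        h2 = model.fit(X, y, config=cfg).history
        assert h1 == h2

    def test_single_class_training_rejected(self, separable_segments):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "noise"))
        with pytest.raises(ConfigurationError):
            model.fit(X[y == "beat"], y[y == "beat"])

    def test_wrong_segment_length_rejected(self, separable_segments):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 1200, 300, n_classes=2), ("beat", "noise"))
        with pytest.raises(ConfigurationError):
            model.fit(X, y)

    def test_unknown_label_rejected(self, separable_segments):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "other"))
        with pytest.raises(ConfigurationError):
            model.fit(X, y)

    def test_summary_mentions_structure(self, separable_segments):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "noise"))
        res = model.fit(X, y, config=TrainConfig(max_epochs=1, seed=0))
        text = res.summary()
        assert "blocks" in text and "300" in text

    def test_save_load_round_trip(self, separable_segments, tmp_path):
        X, y = separable_segments
        model = ConvNet1D(build_spec(3, 600, 300, n_classes=2), ("beat", "noise"))
        res = model.fit(X, y, config=TrainConfig(max_epochs=2, seed=0))
        res.save(tmp_path / "m")
        from cecgkit import ConvNetResults
        loaded = ConvNetResults.load(tmp_path / "m")
        assert np.allclose(loaded.predict_proba(X[:8]), res.predict_proba(X[:8]),
                           atol=1e-6)
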