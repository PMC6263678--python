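"""LSTM-FCN architecture contracts and small-scale training behavior.

Full-scale parameter-recovery runs live in the acceptance tests; here the
network is exercised at toy sizes to keep the checks fast.
"""

import numpy as np
import pytest

from barkline.classifier import (
    EvalReport,
    LSTMFCNConfig,
    TrainedClassifier,
    build_model,
    evaluate,
    sweep_interpolation_factor,
    train,
)
from barkline.datamodel import ValidationError
from barkline.preprocess import PreprocessConfig, preprocess_dataset
from barkline.synth import SynthConfig, generate_dataset
from barkline import _nn

TINY = LSTMFCNConfig(conv_filters=(4, 8, 4), conv_kernel_sizes=(8, 5, 3),
                     lstm_units=3, dropout_after_lstm=0.5, input_length=60,
                     batch_size=16, epochs=5, seed=0)


def _toy_data(n_per_class: int, length: int, seed: int = 0):
    """Well-separated toy sequences: class-specific envelope positions."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    t = np.linspace(0, 1, length)
    for c in range(4):
        for _ in range(n_per_class):
            mu = 0.2 * (c + 1) + rng.normal(0, 0.01)
            X.append(np.exp(-0.5 * ((t - mu) / 0.06) ** 2)
                     + 0.03 * rng.standard_normal(length))
            y.append(c)
    return np.array(X), np.array(y)


class TestBuildModel:
    def test_softmax_output_dimension(self):
        net = build_model(TINY)
        X = np.random.default_rng(0).random((6, 60))
        probs = _nn.softmax(net.forward(X.astype(np.float32), train=False))
        assert probs.shape == (6, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_concatenated_feature_width(self):
        cfg = LSTMFCNConfig(conv_filters=(1, 1, 1), lstm_units=1,
                            input_length=60)
        net = build_model(cfg)
        assert net.head.W.value.shape == (2, 4)

    def test_pooled_width_is_last_filter_count(self):
        net = build_model(TINY)
        assert net.head.W.value.shape == (4 + 3, 4)

    def test_kernel_larger_than_input_rejected(self):
        with pytest.raises(ValidationError):
            LSTMFCNConfig(input_length=5)


class TestTraining:
    def test_smoke_one_epoch(self):
        X, y = _toy_data(2, 60)
        cfg = LSTMFCNConfig(conv_filters=(4, 8, 4), lstm_units=3,
                            input_length=60, epochs=1, batch_size=8, seed=0)
        fitted = train(build_model(cfg), X, y, config=cfg)
        assert len(fitted.history) == 1
        assert set(fitted.history[0]) == {"epoch", "loss", "accuracy"}

    def test_learns_separable_toy_problem(self):
        X, y = _toy_data(15, 60)
        cfg = LSTMFCNConfig(conv_filters=(8, 16, 8), lstm_units=4,
                            dropout_after_lstm=0.2, input_length=60,
                            epochs=120, batch_size=32, seed=1)
        fitted = train(build_model(cfg), X, y, config=cfg)
        assert fitted.history[-1]["accuracy"] > 0.9

    def test_training_deterministic_given_seed(self):
        X, y = _toy_data(4, 60)
        cfg = LSTMFCNConfig(conv_filters=(4, 8, 4), lstm_units=3,
                            input_length=60, epochs=3, batch_size=8, seed=5)
        h1 = train(build_model(cfg), X, y, config=cfg).history
        h2 = train(build_model(cfg), X, y, config=cfg).history
        assert h1 == h2

    def test_single_class_rejected(self):
        X, _ = _toy_data(3, 60)
        y = np.zeros(len(X), dtype=int)
        with pytest.raises(ValidationError, match="2 classes"):
            train(build_model(TINY), X, y, config=TINY)

    def test_width_mismatch_rejected(self):
        X, y = _toy_data(2, 50)
        with pytest.raises(ValidationError, match="input_length"):
            train(build_model(TINY), X, y, config=TINY)

    def test_probabilities_sum_to_one_after_training(self):
        X, y = _toy_data(3, 60)
        fitted = train(build_model(TINY), X, y, config=TINY)
        probs = fitted.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestEvaluate:
    def _fitted(self):
        X, y = _toy_data(3, 60)
        return train(build_model(TINY), X, y, config=TINY), X, y

    def test_confusion_matrix_bookkeeping(self):
        fitted, X, y = self._fitted()
        report = evaluate(fitted, X, y)
        assert report.confusion.sum() == len(y)
        assert report.accuracy == pytest.approx(
            np.trace(report.confusion) / len(y))
        assert np.array_equal(report.confusion.sum(axis=1),
                              np.bincount(y, minlength=4))

    def test_class_name_mismatch_rejected(self):
        fitted, X, y = self._fitted()
        with pytest.raises(ValidationError, match="class names"):
            evaluate(fitted, X, y, class_names=("a", "b", "c", "d"))

    def test_report_serializable(self):
        import json
        fitted, X, y = self._fitted()
        d = evaluate(fitted, X, y).to_dict()
        json.dumps(d)
        assert set(d) == {"accuracy", "per_class", "confusion", "class_names"}


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        X, y = _toy_data(3, 60)
        fitted = train(build_model(TINY), X, y, config=TINY)
        path = fitted.save(tmp_path / "model.npz")
        back = TrainedClassifier.load(path)
        assert np.allclose(back.predict_proba(X), fitted.predict_proba(X))
        assert back.config == fitted.config


class TestSweep:
    def test_single_factor_shape(self, small_synth_ds):
        cfg = LSTMFCNConfig(conv_filters=(4, 8, 4), lstm_units=3,
                            epochs=2, batch_size=32, seed=0)
        rows = sweep_interpolation_factor(small_synth_ds, [1.0], cfg,
                                          split_seed=0)
        assert len(rows) == 1
        assert 0.0 <= rows[0]["accuracy"] <= 1.0

    def test_empty_factor_list_rejected(self, small_synth_ds):
        with pytest.raises(ValidationError):
            sweep_interpolation_factor(small_synth_ds, [], TINY)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full network agree with central
        finite differences on a tiny configuration."""
        cfg = LSTMFCNConfig(conv_filters=(3, 4, 3), conv_kernel_sizes=(8, 5, 3),
                            lstm_units=2, dropout_after_lstm=0.0,
                            input_length=20, seed=0)
        net = build_model(cfg)
        # check in double precision so finite differences are meaningful
        for p in net.params:
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        rng = np.random.default_rng(1)
        X = rng.random((5, 20))
        y = np.array([0, 1, 2, 3, 0])

        def loss():
            probs = _nn.softmax(net.forward(X, train=True))
            return _nn.cross_entropy(probs, y), probs

        base, probs = loss()
        d = probs.copy()
        d[np.arange(5), y] -= 1
        d /= 5
        for p in net.params:
            p.grad[...] = 0.0
        net.backward(d)

        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for p in net.params:
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size),
                                      replace=False):
                old = flat[i]
                flat[i] = old + eps
                up, _ = loss()
                flat[i] = old - eps
                down, _ = loss()
                flat[i] = old
                numeric = (up - down) / (2 * eps)
                assert gflat[i] == pytest.approx(numeric, abs=1e-4)
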