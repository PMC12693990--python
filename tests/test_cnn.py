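import numpy as np
import pytest

from etongue.cnn import (
    CNNConfig,
    ConvLayerSpec,
    build_cnn,
    predict_proba,
    relu,
    softmax,
    train_cnn,
)


class TestActivations:
    def test_relu_examples(self):
        np.testing.assert_array_equal(relu(np.array([-2.0, 0.0, 3.0])), [0.0, 0.0, 3.0])
        np.testing.assert_array_equal(relu(np.array([-1.0, -5.0])), 0.0)

    def test_relu_idempotent(self):
        x = np.random.default_rng(0).normal(size=100)
        np.testing.assert_array_equal(relu(relu(x)), relu(x))

    def test_softmax_rows_sum_to_one(self):
        z = np.random.default_rng(1).normal(size=(10, 5)) * 10
        np.testing.assert_allclose(softmax(z).sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_equal_logits_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros((1, 5)))[0], 0.2, atol=1e-12)

    def test_softmax_closed_form(self):
        # softmax(0, ln 2) = (1/3, 2/3)
        np.testing.assert_allclose(
            softmax(np.array([[0.0, np.log(2.0)]]))[0], [1 / 3, 2 / 3], atol=1e-12
        )

    def test_softmax_shift_invariant(self):
        z = np.random.default_rng(2).normal(size=(4, 5))
        np.testing.assert_allclose(softmax(z), softmax(z + 123.456), atol=1e-9)


#: hand-derived audit for the default network on a 10080 x 1 input:
#: (name, output_length, channels, params) with params = k*C_in*F + F
EXPECTED_AUDIT = [
    ("conv1", 5040, 32, 16 * 1 * 32 + 32),
    ("pool1", 5039, 32, 0),
    ("conv2", 2520, 32, 8 * 32 * 32 + 32),
    ("pool2", 2519, 32, 0),
    ("conv3", 1260, 64, 4 * 32 * 64 + 64),
    ("pool3", 1259, 64, 0),
    ("conv4", 630, 64, 2 * 64 * 64 + 64),
    ("pool4", 629, 64, 0),
    ("flatten", 629 * 64, 1, 0),
    ("dropout", 629 * 64, 1, 0),
    ("dense", 5, 1, 629 * 64 * 5 + 5),
]


class TestArchitecture:
    def test_default_audit_table_exact(self):
        model = build_cnn(CNNConfig(), 10080, 1)
        audit = model.audit()
        got = list(zip(audit["name"], audit["output_length"],
                       audit["output_channels"], audit["n_params"]))
        assert got == EXPECTED_AUDIT
        assert model.n_params == sum(row[3] for row in EXPECTED_AUDIT)

    def test_final_layer_has_five_units(self):
        audit = build_cnn(CNNConfig(), 10080, 1).audit()
        assert audit.iloc[-1]["output_length"] == 5

    def test_multichannel_layout_shapes(self):
        model = build_cnn(CNNConfig(input_layout="multi_6ch"), 1680, 6)
        audit = model.audit()
        assert audit.iloc[0]["output_length"] == 840
        assert audit.iloc[0]["n_params"] == 16 * 6 * 32 + 32

    def test_too_short_input_names_failing_layer(self):
        with pytest.raises(ValueError, match="conv|pool"):
            build_cnn(CNNConfig(), 8, 1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(n_classes=1)
        with pytest.raises(ValueError):
            CNNConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ConvLayerSpec(4, 0)


@pytest.fixture(scope="module")
def tiny_problem():
    """Two sinusoid classes, length-64 single-channel, linearly learnable."""
    rng = np.random.default_rng(0)
    t = np.arange(64) / 64
    X, y = [], []
    for label, freq in ((0, 2.0), (1, 5.0)):
        for _ in range(16):
            X.append(np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)))
            y.append(label)
    X = (np.array(X) + rng.normal(0, 0.05, size=(32, 64)))[:, :, None]
    return X.astype(np.float32), np.array(y)


TINY_CFG = dict(
    conv_layers=(ConvLayerSpec(8, 8), ConvLayerSpec(8, 4)),
    n_classes=2,
    epochs=15,
    batch_size=8,
)


class TestTraining:
    def test_numeric_gradient_agreement(self):
        """Backprop gradients match central differences on a small net."""
        cfg = CNNConfig(conv_layers=(ConvLayerSpec(3, 4), ConvLayerSpec(2, 3)),
                        dropout_rate=0.0, n_classes=3, seed=7)
        m = build_cnn(cfg, 20, 2)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 20, 2)).astype(np.float32)
        Y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 5)]

        def loss():
            p = softmax(m._forward(x, training=True))
            return -(Y * np.log(p + 1e-12)).sum() / len(x), p

        base, p = loss()
        grads = m._backward((p - Y) / len(x))
        worst = 0.0
        for par, g in zip(m._params(), grads):
            flat, gflat = par.reshape(-1), np.asarray(g).reshape(-1)
            for i in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                eps, old = 1e-3, flat[i]
                flat[i] = old + eps
                lp, _ = loss()
                flat[i] = old - eps
                lm, _ = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                worst = max(worst, abs(num - gflat[i]) / max(1e-6, abs(num) + abs(gflat[i])))
        assert worst < 5e-3  # float32 forward passes limit the agreement

    def test_loss_decreases_on_learnable_problem(self, tiny_problem):
        X, y = tiny_problem
        trained = train_cnn(CNNConfig(seed=3, **TINY_CFG), X, y)
        assert trained.trace["loss"].iloc[-1] <= trained.trace["loss"].iloc[0]
        assert trained.trace["accuracy"].iloc[-1] > 0.8
        assert len(trained.trace) == TINY_CFG["epochs"]

    def test_single_class_batch_rejected(self, tiny_problem):
        X, _ = tiny_problem
        with pytest.raises(ValueError):
            train_cnn(CNNConfig(seed=0, **TINY_CFG), X, np.zeros(len(X)))

    def test_identical_seed_identical_weights_digest(self, tiny_problem):
        X, y = tiny_problem
        cfg = CNNConfig(seed=11, **{**TINY_CFG, "epochs": 3})
        d1 = train_cnn(cfg, X, y).model.weights_digest()
        d2 = train_cnn(cfg, X, y).model.weights_digest()
        assert d1 == d2

    def test_accumulation_chunking_preserves_updates(self, tiny_problem):
        """Chunked gradient accumulation gives the same trajectory as one pass."""
        X, y = tiny_problem
        cfg = CNNConfig(seed=4, dropout_rate=0.0, **{**TINY_CFG, "epochs": 2})
        d_full = train_cnn(cfg, X, y, accum_chunk=64).model.weights_digest()
        d_chunk = train_cnn(cfg, X, y, accum_chunk=3).model.weights_digest()
        # float32 summation order differs; compare weights numerically instead
        m1 = train_cnn(cfg, X, y, accum_chunk=64).model
        m2 = train_cnn(cfg, X, y, accum_chunk=3).model
        for p1, p2 in zip(m1._params(), m2._params()):
            np.testing.assert_allclose(p1, p2, atol=1e-4)

    def test_shape_mismatch_rejected(self, tiny_problem):
        X, y = tiny_problem
        model = build_cnn(CNNConfig(seed=0, **TINY_CFG), 128, 1)
        with pytest.raises(ValueError):
            train_cnn(CNNConfig(seed=0, **TINY_CFG), X, y, model=model)


class TestPrediction:
    def test_probabilities_and_labels(self, tiny_problem):
        X, y = tiny_problem
        trained = train_cnn(CNNConfig(seed=3, **{**TINY_CFG, "epochs": 5}), X, y)
        outs = predict_proba(trained, X[:4])
        for o in outs:
            assert o.probabilities.shape == (2,)
            assert o.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            assert o.predicted_label in (0, 1)

    def test_wrong_input_shape_rejected(self, tiny_problem):
        X, y = tiny_problem
        trained = train_cnn(CNNConfig(seed=3, **{**TINY_CFG, "epochs": 2}), X, y)
        with pytest.raises(ValueError):
            predict_proba(trained, np.zeros((2, 32, 1), dtype=np.float32))
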