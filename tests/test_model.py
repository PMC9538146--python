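"""LSTM gate equations, network assembly, training, cross-validation."""

import numpy as np
import pytest

from lagfuse import nn
from lagfuse.exceptions import (ConfigurationError, ShapeError,
                                StratificationError)
from lagfuse.model import (LstmWeights, ModelSpec, MovementDecoder,
                           build_model, lstm_step)


def random_weights(rng, H, D):
    r = lambda *s: rng.standard_normal(s) * 0.5
    return LstmWeights(r(H, D), r(H, D), r(H, D), r(H, D),
                       r(H, H), r(H, H), r(H, H), r(H, H),
                       r(H), r(H), r(H), r(H))


def naive_lstm_step(x, h, c, w):
    """Element-by-element loop evaluation of the gate equations."""
    import math
    H, D = w.W_i.shape
    h_new = np.empty(H)
    c_new = np.empty(H)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    for j in range(H):
        ai = w.b_i[j] + sum(w.W_i[j, d] * x[d] for d in range(D)) \
            + sum(w.U_i[j, k] * h[k] for k in range(H))
        af = w.b_f[j] + sum(w.W_f[j, d] * x[d] for d in range(D)) \
            + sum(w.U_f[j, k] * h[k] for k in range(H))
        ao = w.b_o[j] + sum(w.W_o[j, d] * x[d] for d in range(D)) \
            + sum(w.U_o[j, k] * h[k] for k in range(H))
        ac = w.b_c[j] + sum(w.W_c[j, d] * x[d] for d in range(D)) \
            + sum(w.U_c[j, k] * h[k] for k in range(H))
        c_new[j] = sig(af) * c[j] + sig(ai) * math.tanh(ac)
        h_new[j] = sig(ao) * math.tanh(c_new[j])
    return h_new, c_new


# ---------------------------------------------------------------------------
# gate equations


def test_lstm_step_zero_weights_closed_form():
    H, D = 3, 2
    z = np.zeros
    w = LstmWeights(z((H, D)), z((H, D)), z((H, D)), z((H, D)),
                    z((H, H)), z((H, H)), z((H, H)), z((H, H)),
                    z(H), z(H), z(H), z(H))
    c_prev = np.array([1.0, -2.0, 0.5])
    h, c = lstm_step(np.ones(D), np.zeros(H), c_prev, w)
    assert np.allclose(c, 0.5 * c_prev)
    assert np.allclose(h, 0.5 * np.tanh(0.5 * c_prev))


def test_lstm_step_saturated_forget_gate_drops_past():
    rng = np.random.default_rng(0)
    w = random_weights(rng, 4, 3)
    w.b_f[:] = -50.0                     # forget gate -> 0
    x, h0 = rng.standard_normal(3), rng.standard_normal(4)
    c_prev = rng.standard_normal(4) * 10
    _, c = lstm_step(x, h0, c_prev, w)
    i = nn.sigmoid(w.W_i @ x + w.U_i @ h0 + w.b_i)
    ct = np.tanh(w.W_c @ x + w.U_c @ h0 + w.b_c)
    assert np.allclose(c, i * ct, atol=1e-12)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_lstm_step_matches_naive_loop(seed):
    rng = np.random.default_rng(seed)
    H, D = 5, 4
    w = random_weights(rng, H, D)
    x, h0, c0 = (rng.standard_normal(D), rng.standard_normal(H),
                 rng.standard_normal(H))
    h, c = lstm_step(x, h0, c0, w)
    h_ref, c_ref = naive_lstm_step(x, h0, c0, w)
    assert np.allclose(h, h_ref, atol=1e-6)
    assert np.allclose(c, c_ref, atol=1e-6)


def test_lstm_step_matches_training_backend_cell():
    """The backend's packed-weight cell implements the same equations."""
    rng = np.random.default_rng(4)
    D, H = 6, 5
    layer = nn.LSTMLayer(D, H, rng)
    w = LstmWeights.from_packed(layer.Wx[0], layer.Wh[0], layer.b[0], H)
    x = rng.standard_normal(D)
    h0 = rng.standard_normal(H)
    c0 = rng.standard_normal(H)
    h_layer, c_layer, _ = layer.step(x[None, :], h0[None, :], c0[None, :])
    h_ref, c_ref = lstm_step(x, h0, c0, w)
    assert np.allclose(h_layer[0], h_ref, atol=1e-5)
    assert np.allclose(c_layer[0], c_ref, atol=1e-5)


def test_lstm_step_shape_errors():
    rng = np.random.default_rng(5)
    w = random_weights(rng, 3, 2)
    with pytest.raises(ShapeError):
        lstm_step(np.zeros(5), np.zeros(3), np.zeros(3), w)


# ---------------------------------------------------------------------------
# network assembly


def test_build_model_softmax_and_pooling():
    rng = np.random.default_rng(0)
    spec = ModelSpec(n_classes=4)
    assert spec.pooled_length(200) == 12     # 200 -> 100 -> 50 -> 25 -> 12
    net = build_model(spec, (13, 200), rng)
    probs = nn.softmax(net.forward(rng.standard_normal((3, 13, 200))))
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert probs.shape == (3, 4)


def test_build_model_rejects_too_short_input():
    rng = np.random.default_rng(0)
    with pytest.raises(ConfigurationError):
        build_model(ModelSpec(), (13, 8), rng)
    with pytest.raises(ConfigurationError):
        ModelSpec(conv_blocks=((5, 8, 2),))   # must be 4 blocks


def test_backprop_matches_numeric_gradient():
    """Finite-difference check of the full conv-pool-LSTM-dense chain."""
    rng = np.random.default_rng(7)
    spec = ModelSpec(conv_blocks=((3, 2, 2), (3, 2, 2), (3, 3, 2), (3, 3, 2)),
                     lstm_blocks=((4, 0.0), (4, 0.0)), n_classes=3)
    net = build_model(spec, (2, 32), rng)
    X = rng.standard_normal((4, 2, 32))
    y = np.array([0, 1, 2, 0])

    def loss_value():
        logits = net.forward(X, train=True)
        loss, _ = nn.cross_entropy_grad(logits, y)
        return loss

    net.zero_grad()
    logits = net.forward(X, train=True)
    _, dlogits = nn.cross_entropy_grad(logits, y)
    net.backward(dlogits)

    eps = 1e-6
    checked = 0
    for value, grad in net.params:
        flat_idx = [0, value.size // 2, value.size - 1]
        for fi in flat_idx:
            orig = value.flat[fi]
            value.flat[fi] = orig + eps
            lp = loss_value()
            value.flat[fi] = orig - eps
            lm = loss_value()
            value.flat[fi] = orig
            num = (lp - lm) / (2 * eps)
            assert grad.flat[fi] == pytest.approx(num, rel=1e-3, abs=1e-6)
            checked += 1
    assert checked >= 30


# ---------------------------------------------------------------------------
# training and cross-validation


def tiny_dataset(rng, n_per_class=30, C=3, L=32, n_classes=3, sep=2.0):
    X, y = [], []
    for c in range(n_classes):
        base = np.zeros((C, L))
        base[c % C] = sep
        for _ in range(n_per_class):
            X.append(base + rng.standard_normal((C, L)))
            y.append(c)
    return np.asarray(X), np.asarray(y)


TINY_SPEC = ModelSpec(conv_blocks=((3, 4, 2), (3, 4, 2), (3, 8, 2), (3, 8, 2)),
                      lstm_blocks=((8, 0.2), (8, 0.2)), n_classes=3,
                      epochs=6, batch_size=32)


def test_training_is_seeded_deterministic():
    rng = np.random.default_rng(1)
    X, y = tiny_dataset(rng)
    a = MovementDecoder(X, y, spec=TINY_SPEC).fit(seed=3)
    b = MovementDecoder(X, y, spec=TINY_SPEC).fit(seed=3)
    assert a.loss_history == b.loss_history
    assert all(np.array_equal(u, v) for u, v in
               zip(a.network.state_arrays(), b.network.state_arrays()))


def test_training_learns_separable_classes():
    rng = np.random.default_rng(2)
    X, y = tiny_dataset(rng)
    res = MovementDecoder(X, y, spec=TINY_SPEC).fit(seed=0)
    assert res.score(X, y) > 0.9
    assert res.loss_history[-1] < res.loss_history[0]


def test_kfold_partition_and_report():
    rng = np.random.default_rng(3)
    X, y = tiny_dataset(rng, n_per_class=20)
    dec = MovementDecoder(X, y, spec=TINY_SPEC)
    res = dec.fit_kfold(k=5, seed=0, epochs=3)
    assert len(res.fold_accuracies) == 5
    assert res.confusion.sum() == len(y)          # every sample tested once
    assert np.array_equal(res.confusion.sum(axis=1), [20, 20, 20])
    assert 0.0 <= res.mean_accuracy <= 1.0
    assert "accuracy" in res.summary()


def test_kfold_group_awareness_keeps_epochs_together():
    rng = np.random.default_rng(4)
    X, y = tiny_dataset(rng, n_per_class=20)
    groups = np.arange(len(y)) // 4               # 4 windows per "epoch"
    dec = MovementDecoder(X, y, groups=groups, spec=TINY_SPEC)
    folds = list(dec._splits(5, seed=0))
    for tr, te in folds:
        assert not set(groups[tr]) & set(groups[te])


def test_kfold_stratification_error_on_tiny_data():
    rng = np.random.default_rng(5)
    X, y = tiny_dataset(rng, n_per_class=2)
    with pytest.raises(StratificationError):
        MovementDecoder(X, y, spec=TINY_SPEC).fit_kfold(k=5)


def test_feature_vector_input_is_accepted():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.standard_normal((25, 48)) + 3 * (c == 1)
                   for c in range(2)])
    y = np.repeat([0, 1], 25)
    spec = ModelSpec(conv_blocks=((3, 4, 2), (3, 4, 2), (3, 4, 2), (3, 4, 2)),
                     lstm_blocks=((8, 0.0), (8, 0.0)), n_classes=2,
                     epochs=25, batch_size=16)
    res = MovementDecoder(X, y, spec=spec).fit(seed=0)
    assert res.score(X, y) > 0.9
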