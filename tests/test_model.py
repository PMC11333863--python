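"""Network architecture: shapes, attention semantics, head behavior,
gradient correctness and eval-mode invariants."""

import numpy as np
import pytest

import fallstream.model.layers as L
from fallstream.model.layers import (
    TemporalSelfAttention,
    VectorSelfAttention,
    cross_entropy,
)
from fallstream.model.network import DualStreamNet, ModelConfig, encode_stream, self_attention

N_PARAMS_EXPECTED = 109_058  # regression guard; independent of LoS


def _batch(rng, n=3, los=600):
    return rng.normal(size=(n, los, 3)), rng.normal(size=(n, los, 3))


# --------------------------------------------------------------- encoder
def test_encoder_intermediate_and_output_shapes(rng):
    """Temporal lengths follow LoS -> LoS/2 -> LoS/4 -> global 64-D vector."""
    net = DualStreamNet(ModelConfig(seed=0))
    for los, mid in [(600, 150), (400, 100)]:
        x = rng.normal(size=(2, los, 3)).astype(np.float32)
        feat = encode_stream(x, net.acc_stream)
        assert feat.shape == (2, 64)
        assert net.acc_stream._pre_pool.shape == (2, mid, 64)


def test_encoder_zero_input_zero_bias_gives_zero_features(rng):
    net = DualStreamNet(ModelConfig(seed=1))
    for conv in (net.acc_stream.conv1, net.acc_stream.conv2, net.acc_stream.conv3):
        conv.params["b"][:] = 0
    feat = encode_stream(np.zeros((2, 600, 3)), net.acc_stream)
    np.testing.assert_allclose(feat, 0.0, atol=1e-7)


def test_encoder_rejects_wrong_channel_count(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    with pytest.raises(ValueError, match="channels"):
        net.acc_stream.conv1.forward(rng.normal(size=(2, 600, 5)).astype(np.float32))


# ------------------------------------------------------------- attention
def test_attention_rows_sum_to_one_many_draws():
    """1000 random (parameter, input) draws: every attention row is a
    probability distribution."""
    for pdraw in range(20):
        attn = VectorSelfAttention(64, np.random.default_rng(pdraw))
        x = np.random.default_rng(1000 + pdraw).normal(size=(50, 64)).astype(np.float32)
        out = self_attention(x, attn)
        sums = out.attention.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-6)
        assert (out.attention >= 0).all()


def test_attention_zero_query_gives_uniform_weights(rng):
    attn = VectorSelfAttention(64, rng)
    attn.params["Wq"][:] = 0
    x = rng.normal(size=(4, 64)).astype(np.float32)
    out = self_attention(x, attn)
    np.testing.assert_allclose(out.attention, 1.0 / 64, atol=1e-6)
    v = x @ attn.params["Wv"].T
    expected = np.broadcast_to(v.mean(axis=1, keepdims=True), out.weighted.shape)
    np.testing.assert_allclose(out.weighted, expected, atol=1e-5)


def test_attention_matches_brute_force_loop_oracle():
    """4-D toy reduction with fixed integer weights vs an independent
    double-loop evaluation of the same formula."""
    dim = 4
    attn = VectorSelfAttention(dim, np.random.default_rng(0), temperature=2.0)
    attn.params["Wq"] = np.arange(16, dtype=np.float32).reshape(4, 4) % 3 - 1
    attn.params["Wk"] = (np.arange(16, dtype=np.float32).reshape(4, 4) % 5 - 2) / 2
    attn.params["Wv"] = np.eye(4, dtype=np.float32) * 2
    x = np.array([[0.5, -1.0, 2.0, 0.25]], dtype=np.float32)

    q = attn.params["Wq"].astype(float) @ x[0]
    k = attn.params["Wk"].astype(float) @ x[0]
    v = attn.params["Wv"].astype(float) @ x[0]
    expected_a = np.empty((dim, dim))
    for i in range(dim):
        row = np.array([np.exp(q[i] * k[j] / 2.0) for j in range(dim)])
        expected_a[i] = row / row.sum()
    expected_y = np.array([sum(expected_a[i, j] * v[j] for j in range(dim)) for i in range(dim)])

    out = self_attention(x, attn)
    np.testing.assert_allclose(out.attention[0], expected_a, atol=1e-6)
    np.testing.assert_allclose(out.weighted[0], expected_y, atol=1e-6)


def test_temporal_attention_mode_shapes_and_rows(rng):
    net = DualStreamNet(ModelConfig(seed=0, attention_mode="temporal"))
    acc, gyro = _batch(rng, n=2, los=400)
    probs, diag = net.forward(acc, gyro)
    assert probs.shape == (2, 2)
    a = diag.post_attention["acc"].attention
    assert a.shape == (2, 100, 100)  # LoS/4 temporal positions
    assert np.allclose(a.sum(axis=2), 1.0, atol=1e-5)


# ------------------------------------------------------------------ head
def test_classify_probabilities_sum_to_one(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    probs = net.classify(rng.normal(size=(5, 128)))
    assert probs.shape == (5, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_classify_eval_mode_deterministic_train_mode_not(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    x = rng.normal(size=(8, 128))
    np.testing.assert_array_equal(net.classify(x), net.classify(x))
    # dropout only active in training mode
    a = net.classify(x, train=True)
    b = net.classify(x, train=True)
    assert not np.array_equal(a, b)


def test_classify_zero_weights_gives_even_odds(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    net.fc2.params["W"][:] = 0
    net.fc2.params["b"][:] = 0
    probs = net.classify(rng.normal(size=(3, 128)))
    np.testing.assert_allclose(probs, 0.5, atol=1e-6)


def test_classify_rejects_wrong_dimension(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    with pytest.raises(ValueError):
        net.classify(rng.normal(size=(3, 64)))


# --------------------------------------------------------------- forward
def test_forward_batch_shapes_and_diagnostics(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    acc, gyro = _batch(rng, n=16, los=600)
    probs, diag = net.forward(acc, gyro)
    assert probs.shape == (16, 2)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert diag.pre_attention["acc"].shape == (16, 64)
    assert diag.post_attention["gyro"].weighted.shape == (16, 64)
    assert diag.post_attention["gyro"].attention.shape == (16, 64, 64)


def test_forward_rejects_mismatched_streams(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    with pytest.raises(ValueError):
        net.forward(rng.normal(size=(2, 600, 3)), rng.normal(size=(2, 400, 3)))


def test_batch_permutation_equivariance(rng):
    """Eval mode has no cross-sample coupling: permuting the batch permutes
    the outputs identically."""
    net = DualStreamNet(ModelConfig(seed=0))
    acc, gyro = _batch(rng, n=8, los=400)
    probs, _ = net.forward(acc, gyro)
    perm = rng.permutation(8)
    probs_p, _ = net.forward(acc[perm], gyro[perm])
    np.testing.assert_allclose(probs_p, probs[perm], atol=1e-6)


def test_eval_mode_bit_identical(rng):
    net = DualStreamNet(ModelConfig(seed=0))
    acc, gyro = _batch(rng, n=4, los=400)
    a, _ = net.forward(acc, gyro)
    b, _ = net.forward(acc, gyro)
    np.testing.assert_array_equal(a, b)


def test_streams_are_untied(rng):
    """Swapping acc and gyro inputs changes the output (independent weights)."""
    net = DualStreamNet(ModelConfig(seed=0))
    acc, gyro = _batch(rng, n=4, los=400)
    a, _ = net.forward(acc, gyro)
    b, _ = net.forward(gyro, acc)
    assert not np.allclose(a, b)


def test_parameter_count_regression_guard():
    net600 = DualStreamNet(ModelConfig(seed=0))
    assert net600.n_parameters() == N_PARAMS_EXPECTED
    # architecture constants only: LoS does not enter the count
    probs, _ = net600.forward(np.zeros((1, 400, 3)), np.zeros((1, 400, 3)))
    assert probs.shape == (1, 2)


def test_checkpoint_round_trip(tmp_path, rng):
    net = DualStreamNet(ModelConfig(seed=5))
    net.set_normalization(rng.normal(size=6), np.abs(rng.normal(size=6)) + 0.5)
    acc, gyro = _batch(rng, n=3, los=400)
    before, _ = net.forward(acc, gyro)
    path = tmp_path / "ckpt.npz"
    net.save(path)
    loaded = DualStreamNet.load(path)
    after, _ = loaded.forward(acc, gyro)
    np.testing.assert_array_equal(before, after)
    assert loaded.config == net.config


# ------------------------------------------------------------- gradients
def test_gradients_match_finite_differences(monkeypatch):
    """Whole-network analytic gradients vs central differences (float64,
    dropout disabled; a spot-check per parameter tensor)."""
    monkeypatch.setattr(L, "DTYPE", np.float64)
    net = DualStreamNet(ModelConfig(seed=3))
    net.dropout.p = 0.0
    rng = np.random.default_rng(1)
    acc = rng.normal(size=(3, 8, 3))
    gyro = rng.normal(size=(3, 8, 3))
    y = np.array([0, 1, 1])

    def loss():
        return cross_entropy(net.logits(acc, gyro, train=True), y)

    l0, d = loss()
    net.backward(d)
    grads = {k: v.copy() for k, v in net.gradients().items()}
    params = net.parameters()
    check_rng = np.random.default_rng(0)
    eps = 1e-6
    for key, arr in params.items():
        flat = arr.reshape(-1)
        for i in check_rng.integers(0, flat.size, size=3):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss()
            flat[i] = orig - eps
            lm, _ = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key].reshape(-1)[i]
            assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-3), key


def test_temporal_attention_gradients(monkeypatch):
    monkeypatch.setattr(L, "DTYPE", np.float64)
    rng = np.random.default_rng(0)
    attn = TemporalSelfAttention(5, rng)
    x = rng.normal(size=(2, 6, 5))
    dy = rng.normal(size=(2, 6, 5))

    def loss():
        return float((attn.forward(x, train=True) * dy).sum())

    l0 = loss()
    attn.backward(dy)
    grads = {k: v.copy() for k, v in attn.grads.items()}
    eps = 1e-6
    for key in ("Wq", "Wk", "Wv"):
        flat = attn.params[key].reshape(-1)
        for i in (0, 7, 23):
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            ana = grads[key].reshape(-1)[i]
            assert abs(num - ana) <= 1e-5 * max(abs(num), abs(ana), 1.0)
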