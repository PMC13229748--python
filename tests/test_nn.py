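"""Layer-level correctness: analytic gradients, attention algebra, recurrences."""

import numpy as np
import pytest

from respcam import nn


def numeric_grad(f, arr, eps=1e-6, rng=None, n_probe=6):
    """Central-difference gradient at randomly probed coordinates."""
    flat = arr.ravel()
    idx = (rng or np.random.default_rng(0)).choice(flat.size,
                                                   size=min(n_probe, flat.size),
                                                   replace=False)
    grads = {}
    for i in idx:
        old = flat[i]
        flat[i] = old + eps
        lp = f()
        flat[i] = old - eps
        lm = f()
        flat[i] = old
        grads[int(i)] = (lp - lm) / (2 * eps)
    return grads


def check_layer_grads(layer, x, rng, train=True):
    """Compare analytic parameter and input gradients with finite differences."""
    w = rng.normal(size=layer.forward(x, train=train).shape)

    def loss():
        return float(np.sum(layer.forward(x, train=train) * w))

    for p in layer.parameters():
        p.grad[...] = 0.0
    gx = layer.backward(w)
    for p in layer.parameters():
        for i, num in numeric_grad(loss, p.value, rng=rng).items():
            assert p.grad.ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-7)
    for i, num in numeric_grad(loss, x, rng=rng).items():
        assert gx.ravel()[i] == pytest.approx(num, rel=1e-4, abs=1e-7)


@pytest.fixture()
def g():
    return np.random.default_rng(0)


@pytest.mark.parametrize("make", [
    lambda g: nn.Dense(5, 3, g, np.float64),
    lambda g: nn.Conv1d(3, 4, 3, g, np.float64),
    lambda g: nn.Conv1d(2, 2, 5, g, np.float64),
    lambda g: nn.LayerNorm(6, dtype=np.float64),
    lambda g: nn.BatchNorm1d(4, dtype=np.float64),
    lambda g: nn.MultiHeadAttention(8, 2, 0.0, g, np.float64),
    lambda g: nn.LSTM(3, 4, g, dtype=np.float64),
    lambda g: nn.LSTM(3, 4, g, reverse=True, dtype=np.float64),
    lambda g: nn.BiLSTM(3, 2, g, dtype=np.float64),
], ids=["dense", "conv_k3", "conv_k5", "layernorm", "batchnorm", "attention",
        "lstm_fw", "lstm_bw", "bilstm"])
def test_gradients_match_finite_differences(make, g):
    layer = make(g)
    c_in = {nn.Dense: 5, nn.LayerNorm: 6, nn.BatchNorm1d: 4,
            nn.MultiHeadAttention: 8}.get(type(layer))
    if c_in is None:
        c_in = layer.W.shape[1] if isinstance(layer, nn.Conv1d) else 3
    x = g.normal(size=(2, 6, c_in))
    check_layer_grads(layer, x, g)


class TestConv1d:
    def test_matches_direct_summation(self, g):
        # oracle: y(t) = sum_i w_i x(t-i) + b on a width-1 toy sequence
        conv = nn.Conv1d(1, 1, 3, g, np.float64)
        x = g.normal(size=(1, 5, 1))
        out = conv.forward(x)
        w = conv.W.value[:, 0, 0]
        xp = np.concatenate([[0.0], x[0, :, 0], [0.0]])
        expected = [np.dot(w, xp[t:t + 3]) + conv.b.value[0] for t in range(5)]
        np.testing.assert_allclose(out[0, :, 0], expected, atol=1e-12)

    def test_kernel_one_identity_weights(self, g):
        conv = nn.Conv1d(3, 3, 1, g, np.float64)
        conv.W.value[0] = np.eye(3)
        conv.b.value[:] = 0.0
        x = g.normal(size=(2, 4, 3))
        np.testing.assert_allclose(conv.forward(x), x, atol=1e-12)

    @pytest.mark.parametrize("k", [7, 5, 3])
    def test_length_preserved(self, g, k):
        conv = nn.Conv1d(4, 4, k, g)
        assert conv.forward(g.normal(size=(1, 11, 4)).astype(np.float32)).shape == (1, 11, 4)


class TestAttention:
    def test_single_timestep_passes_value_through(self, g):
        Q, K, V = (g.normal(size=(1, 1, 4)) for _ in range(3))
        np.testing.assert_allclose(nn.scaled_dot_attention(Q, K, V), V, atol=1e-12)

    def test_zero_query_averages_values(self, g):
        K, V = g.normal(size=(3, 4)), g.normal(size=(3, 4))
        out = nn.scaled_dot_attention(np.zeros((3, 4)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (3, 1)), atol=1e-12)

    def test_rows_are_stochastic(self, g):
        mha = nn.MultiHeadAttention(16, 8, 0.0, g)
        x = g.normal(size=(2, 12, 16)).astype(np.float32)
        A = mha.attention_weights(x)
        assert A.shape == (2, 8, 12, 12)
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(A >= 0)

    def test_residual_only_when_output_map_zero(self, g):
        mha = nn.MultiHeadAttention(8, 2, 0.0, g, np.float64)
        mha.Wo.W.value[...] = 0.0
        mha.Wo.b.value[...] = 0.0
        x = g.normal(size=(1, 5, 8))
        np.testing.assert_allclose(mha.forward(x), mha.ln.forward(x), atol=1e-12)

    def test_shape_preserved(self, g):
        mha = nn.MultiHeadAttention(16, 4, 0.0, g)
        x = g.normal(size=(3, 9, 16)).astype(np.float32)
        assert mha.forward(x).shape == x.shape

    def test_head_divisibility_enforced(self, g):
        with pytest.raises(ValueError):
            nn.MultiHeadAttention(10, 4, 0.0, g)


class TestLSTM:
    def test_zero_weights_fixed_point(self, g):
        lstm = nn.LSTM(3, 4, g, dtype=np.float64)
        lstm.W.value[...] = 0.0
        lstm.b.value[...] = 0.0
        out = lstm.forward(g.normal(size=(2, 5, 3)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_hand_stepped_recurrence(self, g):
        # oracle: explicit per-gate recurrence at T=3, width 2
        lstm = nn.LSTM(2, 2, g, dtype=np.float64)
        x = g.normal(size=(1, 3, 2))
        out = lstm.forward(x)

        def sigmoid(z):
            return 1.0 / (1.0 + np.exp(-z))

        W, b = lstm.W.value, lstm.b.value
        h = np.zeros(2)
        c = np.zeros(2)
        for t in range(3):
            z = np.concatenate([x[0, t], h]) @ W + b
            i, f, gg, o = z[0:2], z[2:4], z[4:6], z[6:8]
            c = sigmoid(f) * c + sigmoid(i) * np.tanh(gg)
            h = sigmoid(o) * np.tanh(c)
            np.testing.assert_allclose(out[0, t], h, atol=1e-12)

    def test_bilstm_concatenates_directions(self, g):
        bi = nn.BiLSTM(3, 2, g, dtype=np.float64)
        x = g.normal(size=(2, 5, 3))
        out = bi.forward(x)
        assert out.shape == (2, 5, 4)
        np.testing.assert_allclose(out[..., :2], bi.fw.forward(x))
        np.testing.assert_allclose(out[..., 2:], bi.bw.forward(x))

    def test_time_reversal_symmetry(self, g):
        # running the forward cell on reversed input equals the reversed
        # output of the backward cell with identical weights
        fw = nn.LSTM(3, 2, g, dtype=np.float64)
        bw = nn.LSTM(3, 2, g, reverse=True, dtype=np.float64)
        bw.W.value[...] = fw.W.value
        bw.b.value[...] = fw.b.value
        x = g.normal(size=(1, 4, 3))
        np.testing.assert_allclose(bw.forward(x), fw.forward(x[:, ::-1])[:, ::-1],
                                   atol=1e-12)


class TestDropoutAndNorm:
    def test_dropout_eval_identity(self, g):
        drop = nn.Dropout(0.5, g)
        x = g.normal(size=(2, 4, 3))
        np.testing.assert_array_equal(drop.forward(x, train=False), x)

    def test_dropout_train_scales(self, g):
        drop = nn.Dropout(0.5, g)
        x = np.ones((1, 2000, 1))
        out = drop.forward(x, train=True)
        assert set(np.unique(out)) <= {0.0, 2.0}
        assert out.mean() == pytest.approx(1.0, abs=0.1)

    def test_layernorm_standardizes_each_position(self, g):
        ln = nn.LayerNorm(8, dtype=np.float64)
        x = g.normal(2.0, 3.0, size=(2, 5, 8))
        out = ln.forward(x)
        np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-4)

    def test_batchnorm_eval_uses_frozen_stats(self, g):
        bn = nn.BatchNorm1d(3, dtype=np.float64)
        x = g.normal(5.0, 2.0, size=(4, 10, 3))
        bn.forward(x, train=True)
        y1 = bn.forward(x[:1])
        y2 = bn.forward(x[:1])
        np.testing.assert_array_equal(y1, y2)


class TestOptim:
    def test_adamw_decoupled_decay_shrinks_weights(self):
        p = nn.Parameter(np.array([10.0]))
        opt = nn.AdamW([p], lr=0.1, weight_decay=0.5)
        p.grad[...] = 0.0
        opt.step()
        assert p.value[0] == pytest.approx(10.0 * (1 - 0.1 * 0.5))

    def test_plateau_halves_lr_after_patience(self):
        p = nn.Parameter(np.zeros(1))
        opt = nn.AdamW([p], lr=0.1)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=2)
        sched.step(1.0)
        for _ in range(2):
            assert not sched.step(1.0)
        assert sched.step(1.0)  # third bad epoch triggers the cut
        assert opt.lr == pytest.approx(0.05)
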