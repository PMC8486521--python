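import math

import numpy as np
import pytest

import oracles
from medtext import neural_core as nc

RTOL = 0  # all oracle comparisons are absolute, tolerance 1e-6
ATOL = 1e-6


def _rand_lstm(rng, d, H):
    shape = (H, H + d)
    return nc.LSTMParams(
        W_z=rng.normal(size=shape), W_i=rng.normal(size=shape),
        W_f=rng.normal(size=shape), W_o=rng.normal(size=shape),
        b_z=rng.normal(size=H), b_i=rng.normal(size=H),
        b_f=rng.normal(size=H), b_o=rng.normal(size=H), hidden=H)


def _zero_lstm(d, H):
    shape = (H, H + d)
    z = np.zeros
    return nc.LSTMParams(W_z=z(shape), W_i=z(shape), W_f=z(shape), W_o=z(shape),
                         b_z=z(H), b_i=z(H), b_f=z(H), b_o=z(H), hidden=H)


def _rand_gru(rng, d, H):
    shape = (H, H + d)
    return nc.GRUParams(W_z=rng.normal(size=shape), W_r=rng.normal(size=shape),
                        W=rng.normal(size=shape), hidden=H)


class TestActivations:
    def test_closed_forms(self):
        assert nc.apply_activation("sigmoid", np.array([0.0]))[0] == pytest.approx(0.5)
        assert nc.apply_activation("relu", np.array([-2.5, 3.0])).tolist() == [0.0, 3.0]
        assert nc.apply_activation("softplus", np.array([0.0]))[0] == pytest.approx(math.log(2))
        np.testing.assert_allclose(
            nc.apply_activation("hard_sigmoid", np.array([-10.0, 0.0, 1.0, 10.0])),
            [0.0, 0.5, 0.7, 1.0])
        with pytest.raises(ValueError):
            nc.apply_activation("swish", np.zeros(1))

    def test_sigmoid_derivative_identity(self):
        """sigma' = sigma(1-sigma), checked by finite differences."""
        x = np.linspace(-4, 4, 17)
        h = 1e-6
        num = (nc.apply_activation("sigmoid", x + h) - nc.apply_activation("sigmoid", x - h)) / (2 * h)
        s = nc.apply_activation("sigmoid", x)
        np.testing.assert_allclose(num, s * (1 - s), atol=1e-8)


class TestConv:
    def test_hand_sum(self):
        X = np.array([[1.0], [2.0], [3.0]])
        bank = nc.ConvFilterBank(kernels={2: np.array([[[1.0], [1.0]]])},
                                 biases={2: np.zeros(1)}, activation="linear")
        np.testing.assert_allclose(nc.conv1d_text(X, bank)[0][:, 0], [3.0, 5.0])

    def test_zero_input_zero_map(self):
        rng = np.random.default_rng(0)
        bank = nc.ConvFilterBank.init(rng, [3], 4, 2, activation="tanh", trainable=False)
        bank.biases[3][:] = 0
        maps = nc.conv1d_text(np.zeros((6, 2)), bank)
        np.testing.assert_array_equal(maps[0], 0)

    @pytest.mark.parametrize("trial", range(20))
    def test_nested_loop_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, d = int(rng.integers(4, 9)), int(rng.integers(1, 5))
        bank = nc.ConvFilterBank.init(rng, [2, 3], int(rng.integers(1, 5)), d,
                                      activation="relu", trainable=False)
        for h in bank.widths:
            bank.biases[h] = rng.normal(size=bank.biases[h].shape)
        X = rng.normal(size=(n, d))
        got = nc.conv1d_text(X, bank)
        want = oracles.conv_oracle(X, bank.kernels, bank.biases,
                                   lambda s: max(s, 0.0))
        for g, w in zip(got, want):
            np.testing.assert_allclose(g, w, atol=ATOL)

    def test_too_short_sequence(self):
        bank = nc.ConvFilterBank(kernels={4: np.zeros((1, 4, 1))},
                                 biases={4: np.zeros(1)}, activation="linear")
        with pytest.raises(ValueError):
            nc.conv1d_text(np.zeros((3, 1)), bank)


class TestPool:
    def test_modes(self):
        m = np.array([[1.0], [4.0], [3.0]])
        assert nc.pool_time(m, "max")[0] == 4.0
        assert nc.pool_time(m, "avg")[0] == pytest.approx(8 / 3)
        const = np.full((5, 2), 1.7)
        np.testing.assert_allclose(nc.pool_time(const, "max"), nc.pool_time(const, "avg"))
        with pytest.raises(ValueError):
            nc.pool_time(np.zeros((0, 2)), "max")


class TestLSTM:
    def test_zero_params_closed_form(self):
        p = _zero_lstm(2, 3)
        s = nc.lstm_step(np.zeros(2), nc.LSTMState(h=np.zeros(3), c=np.zeros(3)), p)
        np.testing.assert_array_equal(s.h, 0)
        np.testing.assert_array_equal(s.c, 0)
        s2 = nc.lstm_step(np.zeros(2), nc.LSTMState(h=np.zeros(3), c=np.ones(3)), p)
        np.testing.assert_allclose(s2.c, 0.5)
        np.testing.assert_allclose(s2.h, 0.5 * math.tanh(0.5))

    @pytest.mark.parametrize("trial", range(20))
    def test_scalar_recurrence_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        d, H = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        p = _rand_lstm(rng, d, H)
        x = rng.normal(size=d)
        h0, c0 = rng.normal(size=H), rng.normal(size=H)
        got = nc.lstm_step(x, nc.LSTMState(h=h0, c=c0), p)
        wh, wc = oracles.lstm_scalar_step(
            x, h0, c0, p.W_z, p.W_i, p.W_f, p.W_o, p.b_z, p.b_i, p.b_f, p.b_o)
        np.testing.assert_allclose(got.h, wh, atol=ATOL)
        np.testing.assert_allclose(got.c, wc, atol=ATOL)

    def test_hidden_bounded(self):
        rng = np.random.default_rng(9)
        p = _rand_lstm(rng, 3, 4)
        st = nc.LSTMState(h=rng.normal(size=4), c=rng.normal(size=4) * 100)
        for _ in range(50):
            st = nc.lstm_step(rng.normal(size=3) * 10, st, p)
            assert np.all(np.abs(st.h) <= 1.0)

    def test_sequence_equals_step_iteration(self):
        rng = np.random.default_rng(10)
        p = _rand_lstm(rng, 3, 2)
        X = rng.normal(size=(4, 3))
        outs, final = nc.lstm_sequence(X, p)
        st = nc.LSTMState.zeros(2)
        for t in range(4):
            st = nc.lstm_step(X[t], st, p)
            np.testing.assert_allclose(outs[t], st.h, atol=1e-12)
        np.testing.assert_allclose(final.h, st.h, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_sequence_scalar_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        d, H, T = (int(rng.integers(1, 5)) for _ in range(3))
        p = _rand_lstm(rng, d, H)
        X = rng.normal(size=(T + 1, d))
        outs, _ = nc.lstm_sequence(X, p)
        want, _, _ = oracles.lstm_scalar_sequence(
            X, dict(W_z=p.W_z, W_i=p.W_i, W_f=p.W_f, W_o=p.W_o,
                    b_z=p.b_z, b_i=p.b_i, b_f=p.b_f, b_o=p.b_o), H)
        np.testing.assert_allclose(outs, want, atol=ATOL)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            nc.lstm_sequence(np.zeros((0, 2)), _zero_lstm(2, 2))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nc.lstm_step(np.zeros(5), nc.LSTMState.zeros(3), _zero_lstm(2, 3))


class TestGRU:
    def test_zero_params_closed_forms(self):
        p = nc.GRUParams(W_z=np.zeros((3, 5)), W_r=np.zeros((3, 5)),
                         W=np.zeros((3, 5)), hidden=3)
        np.testing.assert_allclose(nc.gru_step(np.zeros(2), np.ones(3), p), 0.5)
        np.testing.assert_array_equal(nc.gru_step(np.zeros(2), np.zeros(3), p), 0)

    @pytest.mark.parametrize("trial", range(20))
    def test_scalar_oracle(self, trial):
        rng = np.random.default_rng(400 + trial)
        d, H = int(rng.integers(1, 5)), int(rng.integers(1, 5))
        p = _rand_gru(rng, d, H)
        x, h = rng.normal(size=d), rng.normal(size=H)
        got = nc.gru_step(x, h, p)
        want = oracles.gru_scalar_step(x, h, p.W_z, p.W_r, p.W)
        np.testing.assert_allclose(got, want, atol=ATOL)

    def test_convex_combination(self):
        """h_t lies componentwise between h_prev and the candidate."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            p = _rand_gru(rng, 3, 4)
            x, h = rng.normal(size=3), rng.normal(size=4)
            hx = np.concatenate([h, x])
            r = 1 / (1 + np.exp(-p.W_r @ hx))
            cand = np.tanh(p.W @ np.concatenate([r * h, x]))
            out = nc.gru_step(x, h, p)
            lo, hi = np.minimum(h, cand), np.maximum(h, cand)
            assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestBiGRU:
    def test_t1_shared_params(self):
        rng = np.random.default_rng(12)
        g = _rand_gru(rng, 3, 2)
        p = nc.BiGRUParams(forward=g, backward=g)
        x = rng.normal(size=(1, 3))
        out = nc.bigru_sequence(x, p)
        one = nc.gru_step(x[0], np.zeros(2), g)
        np.testing.assert_allclose(out[0], np.concatenate([one, one]), atol=1e-12)

    def test_palindrome_symmetry(self):
        rng = np.random.default_rng(13)
        g = _rand_gru(rng, 2, 3)
        p = nc.BiGRUParams(forward=g, backward=g)
        half = rng.normal(size=(3, 2))
        X = np.concatenate([half, half[::-1]])
        out = nc.bigru_sequence(X, p)
        H = g.hidden
        np.testing.assert_allclose(out[:, :H], out[::-1, H:], atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_two_pass_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        d, H, T = int(rng.integers(1, 5)), int(rng.integers(1, 5)), int(rng.integers(1, 6))
        p = nc.BiGRUParams.init(rng, d, H, trainable=False)
        X = rng.normal(size=(T, d))
        got = nc.bigru_sequence(X, p)
        want = oracles.bigru_oracle(
            X, (p.forward.W_z, p.forward.W_r, p.forward.W),
            (p.backward.W_z, p.backward.W_r, p.backward.W), H)
        np.testing.assert_allclose(got, want, atol=ATOL)


class TestHybridAttention:
    def test_t1_returns_row(self):
        rng = np.random.default_rng(14)
        params = nc.HybridAttentionParams.init(rng, 5, trainable=False)
        H = rng.normal(size=(1, 5))
        ctx, w = nc.hybrid_attention(H, params, return_weights=True)
        np.testing.assert_allclose(w, [1.0])
        np.testing.assert_allclose(ctx, H[0], atol=1e-12)

    def test_identical_rows_uniform(self):
        rng = np.random.default_rng(15)
        params = nc.HybridAttentionParams.init(rng, 4, trainable=False)
        row = rng.normal(size=4)
        H = np.tile(row, (6, 1))
        ctx, w = nc.hybrid_attention(H, params, return_weights=True)
        np.testing.assert_allclose(w, 1 / 6)
        np.testing.assert_allclose(ctx, row, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_direct_formula_oracle(self, trial):
        rng = np.random.default_rng(600 + trial)
        T, m = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        params = nc.HybridAttentionParams.init(rng, m, trainable=False)
        H = rng.normal(size=(T, m))
        ctx, w = nc.hybrid_attention(H, params, return_weights=True)
        want_ctx, want_w = oracles.hybrid_attention_oracle(H, params.W_r, params.v_a, params.b)
        np.testing.assert_allclose(ctx, want_ctx, atol=ATOL)
        np.testing.assert_allclose(w, want_w, atol=ATOL)


class TestScaledDotAttention:
    def test_n1_returns_v(self):
        Q = np.array([[1.0, 2.0]])
        V = np.array([[5.0, -1.0]])
        np.testing.assert_allclose(nc.scaled_dot_attention(Q, Q, V), V)

    def test_identical_keys_average_v(self):
        rng = np.random.default_rng(16)
        K = np.tile(rng.normal(size=3), (5, 1))
        Q = rng.normal(size=(4, 3))
        V = rng.normal(size=(5, 3))
        out = nc.scaled_dot_attention(Q, K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)), atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_nested_loop_oracle(self, trial):
        rng = np.random.default_rng(700 + trial)
        n, d = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        Q, K, V = (rng.normal(size=(n, d)) for _ in range(3))
        np.testing.assert_allclose(nc.scaled_dot_attention(Q, K, V),
                                   oracles.sda_oracle(Q, K, V), atol=ATOL)

    def test_weights_normalized(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n, d = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            Q = rng.normal(size=(n, d))
            _, A = nc.scaled_dot_attention(Q, Q, Q, return_weights=True)
            assert np.all(A >= 0)
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-12)

    def test_key_mask_zeroes_positions(self):
        rng = np.random.default_rng(18)
        Q = rng.normal(size=(3, 4))
        mask = np.array([1.0, 1.0, 0.0])
        _, A = nc.scaled_dot_attention(Q, Q, Q, key_mask=mask, return_weights=True)
        np.testing.assert_allclose(A[:, 2], 0.0, atol=1e-12)
        np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-12)


class TestMultihead:
    def test_identity_reduces_to_sda(self):
        rng = np.random.default_rng(19)
        Q = rng.normal(size=(5, 4))
        p = nc.MultiheadParams.identity(4)
        np.testing.assert_array_equal(nc.multihead_attention(Q, Q, Q, p),
                                      nc.scaled_dot_attention(Q, Q, Q))

    def test_zero_value_projection_zero_output(self):
        rng = np.random.default_rng(20)
        p = nc.MultiheadParams.init(rng, 4, 2, trainable=False)
        p.W_v = [np.zeros_like(w) for w in p.W_v]
        Q = rng.normal(size=(3, 4))
        np.testing.assert_allclose(nc.multihead_attention(Q, Q, Q, p), 0.0, atol=1e-12)

    @pytest.mark.parametrize("trial", range(20))
    def test_per_head_oracle(self, trial):
        rng = np.random.default_rng(800 + trial)
        n_heads = int(rng.choice([1, 2, 4]))
        d_model = n_heads * int(rng.integers(1, 4))
        n = int(rng.integers(1, 8))
        p = nc.MultiheadParams.init(rng, d_model, n_heads, trainable=False)
        Q, K, V = (rng.normal(size=(n, d_model)) for _ in range(3))
        got = nc.multihead_attention(Q, K, V, p)
        want = oracles.multihead_oracle(Q, K, V, p.W_q, p.W_k, p.W_v, p.W_o)
        np.testing.assert_allclose(got, want, atol=ATOL)

    def test_indivisible_dimension_rejected(self):
        with pytest.raises(ValueError):
            nc.MultiheadParams.init(np.random.default_rng(0), 6, 4)


class TestDenseSoftmaxAndLoss:
    def test_uniform_and_closed_form(self):
        p = nc.DenseParams(W=np.zeros((3, 4)), b=np.zeros(3))
        np.testing.assert_allclose(nc.dense_softmax(np.ones(4), p), 1 / 3)
        p2 = nc.DenseParams(W=np.zeros((2, 1)), b=np.array([0.0, math.log(3)]))
        np.testing.assert_allclose(nc.dense_softmax(np.zeros(1), p2), [0.25, 0.75])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(21)
        p = nc.DenseParams.init(rng, 5, 4, trainable=False)
        probs = nc.dense_softmax(rng.normal(size=(7, 5)), p)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_cross_entropy_values(self):
        assert nc.cross_entropy_loss(np.array([[0.0, 1.0]]), [1]) == pytest.approx(0.0, abs=1e-6)
        assert nc.cross_entropy_loss(np.array([[0.5, 0.5]]), [1]) == pytest.approx(math.log(2))
        p = np.array([[0.9, 0.1], [0.2, 0.8], [0.6, 0.4]])
        y = [0, 1, 1]
        per = [nc.cross_entropy_loss(p[i:i + 1], y[i:i + 1]) for i in range(3)]
        assert nc.cross_entropy_loss(p, y) == pytest.approx(np.mean(per))

    def test_binary_form_matches_two_class_formula(self):
        """-mean(y log p1 + (1-y) log(1-p1)) for softmax pairs."""
        rng = np.random.default_rng(22)
        p1 = rng.uniform(0.05, 0.95, size=8)
        p = np.stack([1 - p1, p1], axis=1)
        y = rng.integers(0, 2, size=8)
        want = -np.mean(y * np.log(p1) + (1 - y) * np.log(1 - p1))
        assert nc.cross_entropy_loss(p, y) == pytest.approx(want, abs=1e-6)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            nc.cross_entropy_loss(np.array([[0.5, 0.5]]), [2])


def test_param_serialization_roundtrip(tmp_path):
    rng = np.random.default_rng(23)
    named = {"a.W": rng.normal(size=(3, 2)), "b": rng.normal(size=4)}
    nc.save_params(named, tmp_path / "params")
    back = nc.load_params(tmp_path / "params")
    assert set(back) == set(named)
    for k in named:
        np.testing.assert_array_equal(back[k], named[k])
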