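import numpy as np
import pytest

from medtext import neural_core as nc
from medtext.bigru_mha import BiGRUMHA, BiGRUMHASpec
from medtext.qc_lstm import QCLSTM, QCLSTMSpec
from medtext.tokenize_embed import EncodedBatch


def _batch(rng, n, n_w, n_c, wv, cv, n_classes=2):
    return EncodedBatch(
        word_indices=rng.integers(0, wv, size=(n, n_w)),
        char_indices=rng.integers(0, cv, size=(n, n_c)),
        labels=rng.integers(0, n_classes, size=n),
    )


@pytest.fixture
def qc_setup(rng):
    spec = QCLSTMSpec(n_classes=3, word_vocab_size=30, char_vocab_size=12,
                      n_w=10, n_c=20, word_emb_dim=6, char_emb_dim=4,
                      conv_widths=(1, 3), n_filters=5, lstm_hidden=4,
                      dropout=0.3)
    model = QCLSTM(spec, rng.normal(size=(30, 6)), rng.normal(size=(12, 4)), seed=0)
    batch = _batch(rng, 4, 10, 20, 30, 12, 3)
    return spec, model, batch


class TestQCLSTM:
    def test_output_shape_and_probability_rows(self, qc_setup):
        spec, model, batch = qc_setup
        probs = model.predict_proba(batch)
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0)

    def test_zero_dense_uniform(self, qc_setup):
        spec, model, batch = qc_setup
        model.dense.W.data[:] = 0
        model.dense.b.data[:] = 0
        np.testing.assert_allclose(model.predict_proba(batch), 1 / 3, atol=1e-12)

    def test_duplicate_documents_identical_rows(self, qc_setup, rng):
        spec, model, _ = qc_setup
        one = _batch(rng, 1, 10, 20, 30, 12, 3)
        dup = EncodedBatch(
            word_indices=np.repeat(one.word_indices, 3, axis=0),
            char_indices=np.repeat(one.char_indices, 3, axis=0),
            labels=np.repeat(one.labels, 3),
        )
        probs = model.predict_proba(dup)
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_bitwise_reproducible_without_dropout(self, qc_setup):
        spec, model, batch = qc_setup
        np.testing.assert_array_equal(model.predict_proba(batch),
                                      model.predict_proba(batch))

    def test_parameter_count_closed_form(self, qc_setup):
        """Total parameters equal the hand count over declared shapes."""
        spec, model, batch = qc_setup

        def level_count(V, d):
            conv = sum(spec.n_filters * h * d + spec.n_filters for h in spec.conv_widths)
            H = spec.lstm_hidden
            lstm = 4 * (H * (H + d) + H)
            attn = (2 * H) * (2 * H) + 2 * H + 2 * H
            return V * d + conv + lstm + attn

        merged = 2 * (spec.n_filters * len(spec.conv_widths) + 2 * spec.lstm_hidden)
        expected = (level_count(30, 6) + level_count(12, 4)
                    + spec.n_classes * merged + spec.n_classes)
        assert model.n_parameters() == expected

    def test_word_only_ablation_ignores_chars(self, rng):
        spec = QCLSTMSpec(n_classes=2, word_vocab_size=20, char_vocab_size=8,
                          n_w=8, n_c=12, word_emb_dim=4, char_emb_dim=3,
                          conv_widths=(2,), n_filters=3, lstm_hidden=3,
                          use_char_channels=False)
        model = QCLSTM(spec, rng.normal(size=(20, 4)), rng.normal(size=(8, 3)), seed=1)
        b1 = _batch(rng, 3, 8, 12, 20, 8)
        b2 = EncodedBatch(word_indices=b1.word_indices,
                          char_indices=rng.integers(0, 8, size=(3, 12)),
                          labels=b1.labels)
        np.testing.assert_array_equal(model.predict_proba(b1), model.predict_proba(b2))

    def test_dense_row_permutation_permutes_probs(self, qc_setup):
        spec, model, batch = qc_setup
        base = model.predict_proba(batch)
        perm = np.array([2, 0, 1])
        model.dense.W.data[:] = model.dense.W.data[perm]
        model.dense.b.data[:] = model.dense.b.data[perm]
        np.testing.assert_allclose(model.predict_proba(batch), base[:, perm], atol=1e-12)

    def test_out_of_range_index_rejected(self, qc_setup, rng):
        spec, model, batch = qc_setup
        bad = EncodedBatch(word_indices=np.full((1, 10), 30),
                           char_indices=np.zeros((1, 20), dtype=int),
                           labels=np.zeros(1, dtype=int))
        with pytest.raises(ValueError):
            model.predict_proba(bad)

    def test_dropout_needs_rng_and_perturbs(self, qc_setup):
        spec, model, batch = qc_setup
        with pytest.raises(ValueError):
            model.forward_batch(batch, train=True)
        out = model.forward_batch(batch, train=True, rng=np.random.default_rng(0))
        assert out.data.shape == (4, 3)


@pytest.fixture
def bigru_setup(rng):
    spec = BiGRUMHASpec(n_classes=2, vocab_size=25, n_w=9, emb_dim=5,
                        conv_widths=(1, 2), n_filters=4, hidden=3, layers=2,
                        n_heads=2, dropout=0.4)
    model = BiGRUMHA(spec, rng.normal(size=(25, 5)), seed=2)
    batch = EncodedBatch(word_indices=rng.integers(0, 25, size=(4, 9)),
                         labels=rng.integers(0, 2, size=4))
    return spec, model, batch


class TestBiGRUMHA:
    def test_probability_rows(self, bigru_setup):
        spec, model, batch = bigru_setup
        probs = model.predict_proba(batch)
        assert probs.shape == (4, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_dense_uniform(self, bigru_setup):
        spec, model, batch = bigru_setup
        model.dense.W.data[:] = 0
        model.dense.b.data[:] = 0
        np.testing.assert_allclose(model.predict_proba(batch), 0.5, atol=1e-12)

    def test_duplicate_document_duplicate_row(self, bigru_setup, rng):
        spec, model, _ = bigru_setup
        row = rng.integers(0, 25, size=(1, 9))
        batch = EncodedBatch(word_indices=np.repeat(row, 2, axis=0),
                             labels=np.zeros(2, dtype=int))
        probs = model.predict_proba(batch)
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_stacking_dimensions(self, bigru_setup):
        """Layer k's input width is 2*hidden of layer k-1."""
        spec, model, batch = bigru_setup
        assert model.bigru_stack[0].forward.W_z.data.shape == (3, 3 + 5)
        assert model.bigru_stack[1].forward.W_z.data.shape == (3, 3 + 6)

    def test_parameter_count_closed_form(self, bigru_setup):
        spec, model, batch = bigru_setup
        emb = 25 * 5
        conv = sum(spec.n_filters * h * spec.emb_dim + spec.n_filters
                   for h in spec.conv_widths)
        H = spec.hidden
        gru = lambda d: 3 * H * (H + d)
        bigru = 2 * gru(spec.emb_dim) + 2 * gru(2 * H)
        d_model = 2 * H
        d_head = d_model // spec.n_heads
        mha = 3 * spec.n_heads * d_model * d_head + (spec.n_heads * d_head) * d_model
        merged = 2 * spec.n_filters * len(spec.conv_widths) + 4 * H
        dense = spec.n_classes * merged + spec.n_classes
        assert model.n_parameters() == emb + conv + bigru + mha + dense

    def test_attention_probe_normalized(self, bigru_setup):
        spec, model, batch = bigru_setup
        _, weights = model.forward_batch(batch, return_attention=True)
        assert len(weights) == spec.n_heads
        for A in weights:
            np.testing.assert_allclose(A.data.sum(axis=-1), 1.0, atol=1e-9)
            assert np.all(A.data >= 0)

    def test_identity_single_head_reduces_to_sda(self, rng):
        spec = BiGRUMHASpec(n_classes=2, vocab_size=15, n_w=6, emb_dim=4,
                            conv_widths=(1,), n_filters=2, hidden=2, layers=1,
                            n_heads=1, dropout=0.0)
        model = BiGRUMHA(spec, rng.normal(size=(15, 4)), seed=3)
        model.mha = nc.MultiheadParams.identity(4)
        idx = rng.integers(0, 15, size=(2, 6))
        emb = model.embedding.data[idx]
        seq = nc.bigru_sequence(emb, model.bigru_stack[0])
        att_direct = nc.scaled_dot_attention(seq.data, seq.data, seq.data)
        att_model = nc.multihead_attention(seq.data, seq.data, seq.data, model.mha)
        np.testing.assert_array_equal(att_model, att_direct)

    def test_mask_padding_hides_pad_positions(self, rng):
        spec = BiGRUMHASpec(n_classes=2, vocab_size=15, n_w=6, emb_dim=4,
                            conv_widths=(1,), n_filters=2, hidden=2, layers=1,
                            n_heads=2, dropout=0.0, mask_padding=True)
        model = BiGRUMHA(spec, rng.normal(size=(15, 4)), seed=4)
        idx = rng.integers(1, 15, size=(2, 6))
        idx[:, 4:] = 0  # pad tail
        batch = EncodedBatch(word_indices=idx, labels=np.zeros(2, dtype=int))
        _, weights = model.forward_batch(batch, return_attention=True)
        for A in weights:
            np.testing.assert_allclose(A.data[..., 4:], 0.0, atol=1e-9)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            BiGRUMHASpec(n_classes=2, vocab_size=10, hidden=3, n_heads=4)
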