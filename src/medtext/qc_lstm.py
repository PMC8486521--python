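"""Quad-channel hybrid LSTM classifier.

Four parallel feature channels — {word, char} x {convolution, LSTM} —
over two embedding granularities of the same document:

* per level, the embedded sequence feeds a convolution branch (several
  filter widths, global max pooling over positions) in parallel with an
  LSTM branch whose output sequence is summarized by additive "hybrid"
  attention over the concatenated hidden/cell states [h_t ; c_t];
* the level output is conv ⊕ attended-LSTM; the char-level and
  word-level outputs are concatenated into the merged hidden vector,
  dropout is applied, and a dense softmax produces class probabilities.

The character channels let the model pick up sub-word signal (morphology,
character motifs) that whole-word embeddings cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate
from .neural_core import (
    ConvFilterBank,
    DenseParams,
    HybridAttentionParams,
    LSTMParams,
    conv1d_text,
    dense_softmax,
    hybrid_attention,
    lstm_sequence,
    pool_time,
)
from .tokenize_embed import EmbeddingMatrix, EncodedBatch

__all__ = ["QCLSTMSpec", "QCLSTM", "build_qc_lstm"]


@dataclass(frozen=True)
class QCLSTMSpec:
    n_classes: int
    word_vocab_size: int
    char_vocab_size: int
    n_w: int = 833
    n_c: int = 4998
    word_emb_dim: int = 100
    char_emb_dim: int = 50
    conv_widths: tuple[int, ...] = (1, 3, 5)
    n_filters: int = 200
    lstm_hidden: int = 128
    dropout: float = 0.5
    activation: str = "relu"
    # ablation switches (testing): drop a granularity entirely
    use_word_channels: bool = True
    use_char_channels: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if max(self.conv_widths) > min(self.n_w, self.n_c):
            raise ValueError("conv widths must not exceed the sequence lengths")
        if not (self.use_word_channels or self.use_char_channels):
            raise ValueError("at least one embedding level must be enabled")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class _LevelChannels:
    """conv ‖ LSTM-with-attention over one embedding level."""

    def __init__(self, prefix: str, emb: np.ndarray, spec: QCLSTMSpec,
                 rng: np.random.Generator):
        d = emb.shape[1]
        self.prefix = prefix
        self.embedding = Tensor(np.array(emb, dtype=float), requires_grad=True)
        self.conv = ConvFilterBank.init(rng, spec.conv_widths, spec.n_filters, d,
                                        activation=spec.activation)
        self.lstm = LSTMParams.init(rng, d, spec.lstm_hidden)
        self.attn = HybridAttentionParams.init(rng, 2 * spec.lstm_hidden)

    @property
    def out_dim(self) -> int:
        widths = self.conv.widths
        n_filters = self.conv.kernels[widths[0]].data.shape[0]
        return n_filters * len(widths) + 2 * self.lstm.hidden

    def forward(self, indices: np.ndarray):
        emb = self.embedding[indices]                        # [B, L, d]
        conv_feat = pool_time(conv1d_text(emb, self.conv), "max")
        hs, cs, _ = lstm_sequence(emb, self.lstm, return_cells=True)
        attended = hybrid_attention(concatenate([hs, cs], axis=-1), self.attn)
        return concatenate([conv_feat, attended], axis=-1)

    def params(self) -> dict[str, Tensor]:
        out = {f"{self.prefix}.embedding": self.embedding}
        for h in self.conv.widths:
            out[f"{self.prefix}.conv.k{h}"] = self.conv.kernels[h]
            out[f"{self.prefix}.conv.b{h}"] = self.conv.biases[h]
        for name, t in zip(("W_z", "W_i", "W_f", "W_o", "b_z", "b_i", "b_f", "b_o"),
                           self.lstm.params()):
            out[f"{self.prefix}.lstm.{name}"] = t
        for name, t in zip(("W_r", "v_a", "b"), self.attn.params()):
            out[f"{self.prefix}.attn.{name}"] = t
        return out


class QCLSTM:
    """Assembled quad-channel model; see :func:`build_qc_lstm`."""

    def __init__(self, spec: QCLSTMSpec, word_emb: EmbeddingMatrix | np.ndarray,
                 char_emb: EmbeddingMatrix | np.ndarray, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        word_m = word_emb.matrix if isinstance(word_emb, EmbeddingMatrix) else np.asarray(word_emb)
        char_m = char_emb.matrix if isinstance(char_emb, EmbeddingMatrix) else np.asarray(char_emb)
        if word_m.shape[0] != spec.word_vocab_size:
            raise ValueError("word embedding rows do not match spec.word_vocab_size")
        if char_m.shape[0] != spec.char_vocab_size:
            raise ValueError("char embedding rows do not match spec.char_vocab_size")
        self.levels: dict[str, _LevelChannels] = {}
        if spec.use_char_channels:
            self.levels["char"] = _LevelChannels("char", char_m, spec, rng)
        if spec.use_word_channels:
            self.levels["word"] = _LevelChannels("word", word_m, spec, rng)
        merged_dim = sum(lv.out_dim for lv in self.levels.values())
        self.dense = DenseParams.init(rng, merged_dim, spec.n_classes)

    # -- forward --------------------------------------------------------
    def forward_batch(self, batch: EncodedBatch, train: bool = False,
                      rng: np.random.Generator | None = None):
        """Class-probability rows for an encoded batch.  Deterministic with
        ``train=False``; with ``train=True`` inverted dropout is applied to
        the merged hidden vector using ``rng``."""
        feats = []
        if "char" in self.levels:
            if batch.char_indices is None:
                raise ValueError("model uses char channels but batch has no char indices")
            self._check_indices(batch.char_indices, self.spec.char_vocab_size)
            feats.append(self.levels["char"].forward(batch.char_indices))
        if "word" in self.levels:
            self._check_indices(batch.word_indices, self.spec.word_vocab_size)
            feats.append(self.levels["word"].forward(batch.word_indices))
        h = concatenate(feats, axis=-1) if len(feats) > 1 else feats[0]
        p = self.spec.dropout
        if train and p > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            mask = (rng.random(h.data.shape) >= p) / (1.0 - p)
            h = h * mask
        return dense_softmax(h, self.dense)

    @staticmethod
    def _check_indices(idx: np.ndarray, vocab_size: int) -> None:
        if idx.max(initial=0) >= vocab_size:
            raise ValueError("token index out of range for the model vocabulary")

    def predict_proba(self, batch: EncodedBatch) -> np.ndarray:
        return self.forward_batch(batch, train=False).data

    # -- parameters -----------------------------------------------------
    def params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for lv in self.levels.values():
            out.update(lv.params())
        out["dense.W"] = self.dense.W
        out["dense.b"] = self.dense.b
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params().values())


def build_qc_lstm(spec: QCLSTMSpec, word_emb, char_emb, seed: int = 0) -> QCLSTM:
    """Construct the quad-channel model from a spec and the two embedding
    matrices (word-level and char-level)."""
    return QCLSTM(spec, word_emb, char_emb, seed=seed)
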