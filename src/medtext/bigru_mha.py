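"""Hybrid BiGRU classifier with multihead self-attention.

Two parallel branches over the word-embedded document:

* a text-CNN branch — several filter widths, each feature map reduced by
  BOTH max and average pooling over positions, all concatenated;
* a recurrent branch — a stack of bidirectional GRU layers (layer k
  consumes the 2*hidden-wide output of layer k-1) followed by multihead
  self-attention with Q = K = V = the BiGRU output sequence, itself
  reduced by max+avg pooling over positions.

The branch features are concatenated, dropout is applied, and a dense
softmax produces the class probabilities.  This model uses word-level
input only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .neural_core import (
    BiGRUParams,
    ConvFilterBank,
    DenseParams,
    MultiheadParams,
    bigru_sequence,
    conv1d_text,
    dense_softmax,
    multihead_attention,
    pool_time,
)
from .tokenize_embed import PAD_INDEX, EmbeddingMatrix, EncodedBatch

__all__ = ["BiGRUMHASpec", "BiGRUMHA", "build_bigru_mha"]


@dataclass(frozen=True)
class BiGRUMHASpec:
    n_classes: int
    vocab_size: int
    n_w: int = 833
    emb_dim: int = 100
    conv_widths: tuple[int, ...] = (1, 3, 5)
    n_filters: int = 200
    hidden: int = 128
    layers: int = 2
    n_heads: int = 8
    dropout: float = 0.4
    activation: str = "sigmoid"
    mask_padding: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.layers < 1:
            raise ValueError("need at least one BiGRU layer")
        if (2 * self.hidden) % self.n_heads != 0:
            raise ValueError(
                f"attention model dim {2 * self.hidden} not divisible by "
                f"{self.n_heads} heads")
        if max(self.conv_widths) > self.n_w:
            raise ValueError("conv widths must not exceed the sequence length")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


class BiGRUMHA:
    """Assembled hybrid model; see :func:`build_bigru_mha`."""

    def __init__(self, spec: BiGRUMHASpec, emb: EmbeddingMatrix | np.ndarray,
                 seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        m = emb.matrix if isinstance(emb, EmbeddingMatrix) else np.asarray(emb)
        if m.shape[0] != spec.vocab_size:
            raise ValueError("embedding rows do not match spec.vocab_size")
        if m.shape[1] != spec.emb_dim:
            raise ValueError("embedding dim does not match spec.emb_dim")
        self.embedding = Tensor(np.array(m, dtype=float), requires_grad=True)
        self.conv = ConvFilterBank.init(rng, spec.conv_widths, spec.n_filters,
                                        spec.emb_dim, activation=spec.activation)
        # layer k's input is the 2*hidden output of layer k-1
        self.bigru_stack = [
            BiGRUParams.init(rng, spec.emb_dim if k == 0 else 2 * spec.hidden,
                             spec.hidden)
            for k in range(spec.layers)
        ]
        self.mha = MultiheadParams.init(rng, 2 * spec.hidden, spec.n_heads)
        merged = 2 * spec.n_filters * len(spec.conv_widths) + 4 * spec.hidden
        self.dense = DenseParams.init(rng, merged, spec.n_classes)

    def forward_batch(self, batch: EncodedBatch, train: bool = False,
                      rng: np.random.Generator | None = None,
                      return_attention: bool = False):
        idx = batch.word_indices
        if idx.max(initial=0) >= self.spec.vocab_size:
            raise ValueError("token index out of range for the model vocabulary")
        emb = self.embedding[idx]                                  # [B, T, d]

        maps = conv1d_text(emb, self.conv)
        cnn_feat = concatenate(
            [pool_time(maps, "max"), pool_time(maps, "avg")], axis=-1)

        seq = emb
        for layer in self.bigru_stack:
            seq = bigru_sequence(seq, layer)                       # [B, T, 2H]
        mask = (idx != PAD_INDEX).astype(float) if self.spec.mask_padding else None
        attended = multihead_attention(seq, seq, seq, self.mha, key_mask=mask,
                                       return_weights=return_attention)
        if return_attention:
            attended, weights = attended
        attn_feat = concatenate(
            [pool_time(attended, "max"), pool_time(attended, "avg")], axis=-1)

        h = concatenate([cnn_feat, attn_feat], axis=-1)
        p = self.spec.dropout
        if train and p > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            m = (rng.random(h.data.shape) >= p) / (1.0 - p)
            h = h * m
        probs = dense_softmax(h, self.dense)
        return (probs, weights) if return_attention else probs

    def predict_proba(self, batch: EncodedBatch) -> np.ndarray:
        return self.forward_batch(batch, train=False).data

    def params(self) -> dict[str, Tensor]:
        out = {"embedding": self.embedding}
        for h in self.conv.widths:
            out[f"conv.k{h}"] = self.conv.kernels[h]
            out[f"conv.b{h}"] = self.conv.biases[h]
        for k, layer in enumerate(self.bigru_stack):
            for direction, gp in (("fwd", layer.forward), ("bwd", layer.backward)):
                for name, t in zip(("W_z", "W_r", "W"), gp.params()):
                    out[f"bigru{k}.{direction}.{name}"] = t
        for i in range(self.mha.n_heads):
            out[f"mha.W_q{i}"] = self.mha.W_q[i]
            out[f"mha.W_k{i}"] = self.mha.W_k[i]
            out[f"mha.W_v{i}"] = self.mha.W_v[i]
        out["mha.W_o"] = self.mha.W_o
        out["dense.W"] = self.dense.W
        out["dense.b"] = self.dense.b
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.params().values())


def build_bigru_mha(spec: BiGRUMHASpec, emb, seed: int = 0) -> BiGRUMHA:
    """Construct the hybrid BiGRU / multihead-attention model from a spec
    and the word-level embedding matrix."""
    return BiGRUMHA(spec, emb, seed=seed)
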