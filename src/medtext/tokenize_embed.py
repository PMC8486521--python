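"""Tokenization, vocabularies, fixed-length encoding and skip-gram
embeddings.

Two embedding granularities are supported, mirroring the dual word-level /
character-level encoding of the quad-channel classifier: word tokens are
whitespace-split, character tokens are the individual characters of the
normalized text (spaces included, so word boundaries stay visible to the
character channels).

Embeddings are trained with skip-gram + negative sampling — the center
word predicts its window context; each positive pair is contrasted
against ``negatives`` draws from the unigram^0.75 noise distribution —
implemented directly on numpy with vectorized minibatch SGD.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import LabeledCorpus

__all__ = [
    "PAD", "UNK", "PAD_INDEX", "UNK_INDEX",
    "Vocabulary", "EncodedBatch", "EmbeddingMatrix", "SkipGramConfig",
    "tokenize", "build_vocab", "encode_pad", "encode_corpus",
    "train_skipgram", "cosine_similarity",
    "save_embeddings_text", "load_embeddings_text",
]

PAD, UNK = "<pad>", "<unk>"
PAD_INDEX, UNK_INDEX = 0, 1


def tokenize(text: str, level: str) -> list[str]:
    """Split normalized text into tokens: word level on whitespace, char
    level into single characters (spaces kept as tokens).  Empty text
    gives an empty sequence."""
    if level == "word":
        return text.split()
    if level == "char":
        return list(text)
    raise ValueError(f"unknown tokenization level {level!r}")


@dataclass
class Vocabulary:
    """token <-> contiguous index map with reserved pad=0 and unk=1."""

    level: str
    index_to_token: list[str]
    token_to_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.index_to_token[:2] != [PAD, UNK]:
            raise ValueError("indices 0 and 1 are reserved for pad/unk")
        if not self.token_to_index:
            self.token_to_index = {t: i for i, t in enumerate(self.index_to_token)}
        if len(self.token_to_index) != len(self.index_to_token):
            raise ValueError("duplicate tokens in vocabulary")

    @property
    def size(self) -> int:
        return len(self.index_to_token)

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def token(self, index: int) -> str:
        return self.index_to_token[index]


def build_vocab(corpus: LabeledCorpus, level: str, min_count: int = 1) -> Vocabulary:
    """Frequency-ordered vocabulary (ties broken lexicographically);
    tokens rarer than ``min_count`` are dropped and will encode as unk."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for doc in corpus:
        counts.update(tokenize(doc.text, level))
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    return Vocabulary(level=level, index_to_token=[PAD, UNK] + kept)


def encode_pad(tokens: Sequence[str], vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Map tokens to indices (unk for out-of-vocabulary), truncating at the
    tail beyond ``max_len`` and padding the tail with pad=0."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    out = np.zeros(max_len, dtype=np.int64)
    for i, tok in enumerate(tokens[:max_len]):
        out[i] = vocab.index(tok)
    return out


@dataclass
class EncodedBatch:
    """Fixed-length padded index matrices plus integer labels."""

    word_indices: np.ndarray            # [batch, n_w]
    labels: np.ndarray                  # [batch]
    char_indices: np.ndarray | None = None  # [batch, n_c]

    def __post_init__(self) -> None:
        if self.word_indices.shape[0] != self.labels.shape[0]:
            raise ValueError("batch size mismatch between indices and labels")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def n_w(self) -> int:
        return self.word_indices.shape[1]

    @property
    def n_c(self) -> int | None:
        return None if self.char_indices is None else self.char_indices.shape[1]

    def take(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(
            word_indices=self.word_indices[idx],
            labels=self.labels[idx],
            char_indices=None if self.char_indices is None else self.char_indices[idx],
        )


def encode_corpus(
    corpus: LabeledCorpus,
    word_vocab: Vocabulary,
    n_w: int,
    char_vocab: Vocabulary | None = None,
    n_c: int | None = None,
) -> EncodedBatch:
    """Encode every document at word level (and optionally char level)."""
    words = np.stack([encode_pad(tokenize(d.text, "word"), word_vocab, n_w)
                      for d in corpus])
    chars = None
    if char_vocab is not None:
        if n_c is None:
            raise ValueError("n_c required when char_vocab is given")
        chars = np.stack([encode_pad(tokenize(d.text, "char"), char_vocab, n_c)
                          for d in corpus])
    return EncodedBatch(word_indices=words, labels=corpus.labels_as_indices(),
                        char_indices=chars)


@dataclass
class EmbeddingMatrix:
    """Lookup table [vocab size, d] tied to its vocabulary."""

    level: str
    matrix: np.ndarray
    vocab: Vocabulary
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.vocab.size:
            raise ValueError("row count must equal vocabulary size")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.vocab.index(token)]


@dataclass(frozen=True)
class SkipGramConfig:
    """Skip-gram with negative sampling: embedding dim ``d``, context
    radius ``window`` (tokens), ``negatives`` noise draws per positive
    pair, SGD ``lr`` with linear decay over ``epochs``."""

    d: int = 100
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    lr: float = 0.025
    seed: int = 0
    batch_size: int = 4096

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        if min(self.window, self.negatives + 1, self.lr) <= 0 or self.epochs < 0:
            raise ValueError("window/negatives/lr must be positive, epochs >= 0")


def _context_pairs(seqs: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for seq in seqs:
        n = len(seq)
        for off in range(1, window + 1):
            if n <= off:
                continue
            centers.append(seq[:-off]); contexts.append(seq[off:])
            centers.append(seq[off:]);  contexts.append(seq[:-off])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def train_skipgram(
    corpus: LabeledCorpus,
    level: str,
    config: SkipGramConfig,
    vocab: Vocabulary | None = None,
) -> EmbeddingMatrix:
    """Train skip-gram embeddings with negative sampling.

    Fully seeded: initialization, pair shuffling and noise draws all come
    from ``config.seed``.  ``epochs=0`` returns the seeded random
    initialization unchanged.  The per-epoch mean negative-sampling loss
    is recorded on the returned matrix's ``loss_history``.
    """
    if vocab is None:
        vocab = build_vocab(corpus, level)
    rng = np.random.default_rng(config.seed)
    V, d = vocab.size, config.d
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    seqs = [np.array([vocab.index(t) for t in tokenize(doc.text, level)], dtype=np.int64)
            for doc in corpus]
    centers, contexts = _context_pairs(seqs, config.window)
    if config.epochs > 0 and centers.size == 0:
        raise ValueError("no context pairs: every document has fewer than 2 tokens")

    # unigram^0.75 noise distribution over non-pad entries
    freq = np.bincount(np.concatenate(seqs) if seqs else np.empty(0, np.int64),
                       minlength=V).astype(float)
    freq[PAD_INDEX] = 0.0
    noise = freq**0.75
    noise_sum = noise.sum()
    noise = noise / noise_sum if noise_sum > 0 else None

    history: list[float] = []
    n_pairs = centers.size
    for epoch in range(config.epochs):
        lr = config.lr * max(0.1, 1.0 - epoch / max(1, config.epochs))
        order = rng.permutation(n_pairs)
        total_loss, total_terms = 0.0, 0
        for lo in range(0, n_pairs, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            c, o = centers[idx], contexts[idx]
            neg = rng.choice(V, size=(idx.size, config.negatives), p=noise)
            v_c = W_in[c]                                   # [B, d]
            u_o = W_out[o]                                  # [B, d]
            u_n = W_out[neg]                                # [B, k, d]

            s_pos = _sigmoid(np.einsum("bd,bd->b", v_c, u_o))
            s_neg = _sigmoid(-np.einsum("bd,bkd->bk", v_c, u_n))
            total_loss += -np.log(np.clip(s_pos, 1e-10, None)).sum() \
                          - np.log(np.clip(s_neg, 1e-10, None)).sum()
            total_terms += idx.size

            g_pos = (s_pos - 1.0)[:, None]                  # d/d(score)
            g_neg = (1.0 - s_neg)[:, :, None]
            grad_vc = g_pos * u_o + np.einsum("bk,bkd->bd", g_neg[..., 0], u_n)
            grad_uo = g_pos * v_c
            grad_un = g_neg * v_c[:, None, :]

            np.add.at(W_in, c, -lr * grad_vc)
            np.add.at(W_out, o, -lr * grad_uo)
            np.add.at(W_out, neg.ravel(), -lr * grad_un.reshape(-1, d))
        history.append(float(total_loss) / max(1, total_terms))

    return EmbeddingMatrix(level=level, matrix=W_in, vocab=vocab,
                           loss_history=history)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); rejects zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def save_embeddings_text(emb: EmbeddingMatrix, path: str | Path) -> None:
    """word2vec text format: header 'vocab_size d', then token + d floats
    per line.  Space characters (char level) are escaped as '<space>'."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{emb.vocab.size} {emb.d}\n")
        for i, tok in enumerate(emb.vocab.index_to_token):
            name = "<space>" if tok == " " else tok
            vals = " ".join(f"{x:.6g}" for x in emb.matrix[i])
            fh.write(f"{name} {vals}\n")


def load_embeddings_text(path: str | Path, level: str = "word") -> EmbeddingMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        V, d = int(header[0]), int(header[1])
        tokens, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tok = parts[0]
            tokens.append(" " if tok == "<space>" else tok)
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != V:
        raise ValueError(f"{path}: expected {V} rows, found {len(tokens)}")
    matrix = np.array(rows, dtype=float)
    if matrix.shape != (V, d):
        raise ValueError(f"{path}: expected shape {(V, d)}, got {matrix.shape}")
    vocab = Vocabulary(level=level, index_to_token=tokens)
    return EmbeddingMatrix(level=level, matrix=matrix, vocab=vocab)
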