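"""End-to-end study pipelines at reduced scale.

The full-size configurations (833-token documents, 200 filters, hidden
size 128, batch 512) are impractical for routine verification, so the
package defines one fixed reduced configuration — embedding 16, hidden
16, word length 64, char length 128, 16 filters of widths (1, 3, 5),
batch 32, 2000 two-class synthetic documents split 0.7/0.2/0.1 — and runs
both architectures through it.  Everything here is seeded end to end:
corpus generation, splitting, embedding init, model init, shuffling and
dropout all derive from one run seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bigru_mha import BiGRUMHA, BiGRUMHASpec, build_bigru_mha
from .corpus_io import LabeledCorpus, SplitSpec, split_corpus
from .qc_lstm import QCLSTM, QCLSTMSpec, build_qc_lstm
from .synthetic_data import SynthSpec, generate_corpus
from .tokenize_embed import (
    EncodedBatch,
    SkipGramConfig,
    build_vocab,
    encode_corpus,
    train_skipgram,
)
from .train_eval import (
    MetricsReport,
    TrainConfig,
    TrainHistory,
    evaluate_model,
    grid_sweep,
    train_model,
)

__all__ = [
    "REDUCED", "ReducedConfig", "DataBundle",
    "reduced_synth_spec", "prepare_bundle", "build_reduced_model",
    "run_reduced_training", "run_family_sweep",
]


@dataclass(frozen=True)
class ReducedConfig:
    n_docs: int = 2000
    n_classes: int = 2
    n_w: int = 64
    n_c: int = 128
    emb_dim: int = 16
    hidden: int = 16
    conv_widths: tuple[int, ...] = (1, 3, 5)
    n_filters: int = 16
    n_heads: int = 4
    bigru_layers: int = 1
    batch_size: int = 32
    epochs: int = 10
    patience: int = 3
    learning_rate: float = 0.01
    optimizer: str = "adam"
    dropout: float = 0.2


REDUCED = ReducedConfig()


def reduced_synth_spec(seed: int, char_only: bool = False,
                       cfg: ReducedConfig = REDUCED) -> SynthSpec:
    """The reduced study corpus: noiseless and two-class.  With
    ``char_only`` the word-keyword signal is removed and every token
    carries the class character motif, so only character-level encoders
    can separate the classes."""
    base = SynthSpec(n_docs=cfg.n_docs, n_classes=cfg.n_classes,
                     label_noise=0.0, seed=seed)
    if char_only:
        base = replace(base, keyword_rate=0.0, char_signal_rate=1.0)
    return base


@dataclass
class DataBundle:
    train: EncodedBatch
    val: EncodedBatch
    test: EncodedBatch
    word_emb: np.ndarray
    char_emb: np.ndarray
    word_vocab_size: int
    char_vocab_size: int

    def splits(self) -> dict[str, EncodedBatch]:
        return {"train": self.train, "val": self.val, "test": self.test}


def prepare_bundle(corpus: LabeledCorpus, seed: int,
                   cfg: ReducedConfig = REDUCED,
                   skipgram_epochs: int = 0) -> DataBundle:
    """Split, build vocabularies on the training split, initialize
    embeddings by skip-gram (``skipgram_epochs=0`` keeps the seeded random
    initialization; the models fine-tune their embedding tables during
    training either way) and encode every split at both levels."""
    train_c, val_c, test_c = split_corpus(corpus, SplitSpec(seed=seed))
    word_vocab = build_vocab(train_c, "word")
    char_vocab = build_vocab(train_c, "char")
    word_emb = train_skipgram(
        train_c, "word",
        SkipGramConfig(d=cfg.emb_dim, epochs=skipgram_epochs, window=2, seed=seed),
        vocab=word_vocab)
    char_emb = train_skipgram(
        train_c, "char",
        SkipGramConfig(d=cfg.emb_dim, epochs=skipgram_epochs, window=2, seed=seed + 1),
        vocab=char_vocab)
    enc = {}
    for name, part in (("train", train_c), ("val", val_c), ("test", test_c)):
        enc[name] = encode_corpus(part, word_vocab, cfg.n_w, char_vocab, cfg.n_c)
    return DataBundle(train=enc["train"], val=enc["val"], test=enc["test"],
                      word_emb=word_emb.matrix, char_emb=char_emb.matrix,
                      word_vocab_size=word_vocab.size,
                      char_vocab_size=char_vocab.size)


def build_reduced_model(family: str, bundle: DataBundle, seed: int,
                        cfg: ReducedConfig = REDUCED,
                        word_only: bool = False,
                        **spec_overrides):
    """Fresh model in the reduced configuration.  ``family`` is
    ``qc_lstm`` or ``bigru_mha``; ``word_only`` disables the character
    channels of the quad model (ablation)."""
    if family == "qc_lstm":
        kwargs = dict(
            n_classes=cfg.n_classes,
            word_vocab_size=bundle.word_vocab_size,
            char_vocab_size=bundle.char_vocab_size,
            n_w=cfg.n_w, n_c=cfg.n_c,
            word_emb_dim=cfg.emb_dim, char_emb_dim=cfg.emb_dim,
            conv_widths=cfg.conv_widths, n_filters=cfg.n_filters,
            lstm_hidden=cfg.hidden, dropout=cfg.dropout,
            use_char_channels=not word_only)
        kwargs.update(spec_overrides)
        return build_qc_lstm(QCLSTMSpec(**kwargs), bundle.word_emb,
                             bundle.char_emb, seed=seed)
    if family == "bigru_mha":
        kwargs = dict(
            n_classes=cfg.n_classes,
            vocab_size=bundle.word_vocab_size,
            n_w=cfg.n_w, emb_dim=cfg.emb_dim,
            conv_widths=cfg.conv_widths, n_filters=cfg.n_filters,
            hidden=cfg.hidden, layers=cfg.bigru_layers,
            n_heads=cfg.n_heads, dropout=cfg.dropout)
        kwargs.update(spec_overrides)
        return build_bigru_mha(BiGRUMHASpec(**kwargs), bundle.word_emb, seed=seed)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class ReducedRun:
    history: TrainHistory
    test_metrics: MetricsReport
    best_val_accuracy: float


def run_reduced_training(family: str, seed: int,
                         cfg: ReducedConfig = REDUCED,
                         char_only: bool = False,
                         word_only: bool = False,
                         corpus: LabeledCorpus | None = None,
                         bundle: DataBundle | None = None) -> ReducedRun:
    """Generate (or reuse) the reduced corpus, train one model and return
    its history plus test metrics."""
    if bundle is None:
        if corpus is None:
            corpus = generate_corpus(reduced_synth_spec(seed, char_only=char_only, cfg=cfg))
        bundle = prepare_bundle(corpus, seed, cfg=cfg)
    model = build_reduced_model(family, bundle, seed, cfg=cfg, word_only=word_only)
    tc = TrainConfig(batch_size=cfg.batch_size, optimizer=cfg.optimizer,
                     learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                     patience=cfg.patience, seed=seed)
    history = train_model(model, bundle.train, bundle.val, tc)
    metrics = evaluate_model(model, bundle.test)
    return ReducedRun(history=history, test_metrics=metrics,
                      best_val_accuracy=history.best_val_accuracy())


def run_family_sweep(family: str, axis: str, values, seed: int,
                     cfg: ReducedConfig = REDUCED,
                     bundle: DataBundle | None = None):
    """Hyperparameter sweep over one axis for a model family on the
    reduced corpus, one train+evaluate per value (same seed per cell)."""
    if bundle is None:
        corpus = generate_corpus(reduced_synth_spec(seed, cfg=cfg))
        bundle = prepare_bundle(corpus, seed, cfg=cfg)
    base = TrainConfig(batch_size=cfg.batch_size, optimizer=cfg.optimizer,
                       learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                       patience=cfg.patience, seed=seed)

    def build(value, bseed):
        overrides = {}
        if axis == "kernel_widths":
            overrides["conv_widths"] = tuple(value)
        elif axis == "dropout":
            overrides["dropout"] = float(value)
        elif axis == "activation":
            overrides["activation"] = str(value)
        elif axis == "bigru_layers":
            if family != "bigru_mha":
                raise ValueError("bigru_layers axis applies to bigru_mha only")
            overrides["layers"] = int(value)
        return build_reduced_model(family, bundle, bseed, cfg=cfg, **overrides)

    return grid_sweep(build, axis, values, bundle.splits(), base)
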