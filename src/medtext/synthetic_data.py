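"""Synthetic labeled corpora with controllable word- and character-level
class signal.

Documents are sequences of random lowercase "background" tokens carrying
no class information.  Two independent kinds of signal can be injected:

* word keywords — each class owns a disjoint set of keyword tokens that
  replace background tokens at ``keyword_rate``;
* character motifs — each class owns a short character string embedded
  *inside* otherwise-random tokens at ``char_signal_rate``, so the signal
  is invisible at the whole-word level (every such token is unique) but
  detectable by character-level encoders.

Labels are re-drawn uniformly over the classes at ``label_noise`` (so a
"noisy" document keeps its true label with probability
(1-noise) + noise/n_classes).  Class counts are exactly balanced (±1) and
everything is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Document, LabeledCorpus

__all__ = ["SynthSpec", "generate_corpus", "separability_check", "keyword_rule_labels"]

_LETTERS = np.array(list("abcdefghijklmnopqrstuvwxyz"))


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings; defaults describe a moderately hard two-class
    corpus with both word and character signal."""

    n_docs: int = 2000
    n_classes: int = 2
    doc_len_range: tuple[int, int] = (100, 300)
    background_vocab: int = 1000
    keywords_per_class: int = 10
    keyword_rate: float = 0.05       # per-token probability of a class keyword
    char_motif_len: int = 4          # length of each class's character motif
    char_signal_rate: float = 0.05   # per-token probability of a motif carrier
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must lie in [0, 1)")
        for r in (self.keyword_rate, self.char_signal_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not (3 <= self.char_motif_len <= 6):
            raise ValueError("char motifs must be 3-6 characters long")
        lo, hi = self.doc_len_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid doc_len_range")


def _random_token(rng: np.random.Generator, lo: int = 3, hi: int = 8) -> str:
    n = rng.integers(lo, hi + 1)
    return "".join(rng.choice(_LETTERS, size=n))


def _make_keywords(rng: np.random.Generator, spec: SynthSpec) -> list[list[str]]:
    """Disjoint per-class keyword sets, distinct from background tokens by
    construction (prefixed stems)."""
    sets: list[list[str]] = []
    used: set[str] = set()
    for c in range(spec.n_classes):
        kws = []
        while len(kws) < spec.keywords_per_class:
            w = f"kw{c}" + _random_token(rng, 3, 6)
            if w not in used:
                used.add(w)
                kws.append(w)
        sets.append(kws)
    return sets


def _make_motifs(rng: np.random.Generator, spec: SynthSpec) -> list[str]:
    motifs: list[str] = []
    while len(motifs) < spec.n_classes:
        m = "".join(rng.choice(_LETTERS, size=spec.char_motif_len))
        # motifs must not contain each other, or the char signal is ambiguous
        if all(m not in o and o not in m for o in motifs):
            motifs.append(m)
    return motifs


def _motif_carrier(rng: np.random.Generator, motif: str) -> str:
    """A fresh random token with the motif embedded at a random offset.

    The random flanks are 2-4 characters each so carrier tokens almost
    never repeat across documents: the motif must stay invisible to
    whole-word encoders (a repeated carrier would be a word-level class
    cue) and detectable only at the character level.
    """
    pre = _random_token(rng, 2, 4)
    post = _random_token(rng, 2, 4)
    return pre + motif + post


def generate_corpus(spec: SynthSpec,
                    keyword_sets: list[Sequence[str]] | None = None) -> LabeledCorpus:
    """Draw a corpus per the spec; the keyword sets and motifs used are
    attached to the returned corpus as ``keyword_sets`` / ``char_motifs``
    so the separability check can score against them.  Caller-supplied
    ``keyword_sets`` (one list per class) must be pairwise disjoint."""
    rng = np.random.default_rng(spec.seed)
    background = []
    seen: set[str] = set()
    while len(background) < spec.background_vocab:
        t = _random_token(rng)
        if t not in seen:
            seen.add(t)
            background.append(t)
    background = np.array(background)
    if keyword_sets is None:
        keyword_sets = _make_keywords(rng, spec)
    else:
        if len(keyword_sets) != spec.n_classes:
            raise ValueError("need one keyword set per class")
        keyword_sets = [list(k) for k in keyword_sets]
        flat = [w for kws in keyword_sets for w in kws]
        if len(set(flat)) != len(flat):
            raise ValueError("keyword sets must be pairwise disjoint")
    motifs = _make_motifs(rng, spec)

    # exactly balanced generating labels (±1), then shuffled
    true_labels = np.array([i % spec.n_classes for i in range(spec.n_docs)])
    rng.shuffle(true_labels)

    docs: list[Document] = []
    for i, cls in enumerate(true_labels):
        n_tok = int(rng.integers(spec.doc_len_range[0], spec.doc_len_range[1] + 1))
        toks = list(rng.choice(background, size=n_tok))
        u = rng.random(n_tok)
        kw_slots = np.flatnonzero(u < spec.keyword_rate)
        for j in kw_slots:
            toks[j] = keyword_sets[cls][rng.integers(len(keyword_sets[cls]))]
        v = rng.random(n_tok)
        motif_slots = np.flatnonzero((v < spec.char_signal_rate) & (u >= spec.keyword_rate))
        for j in motif_slots:
            toks[j] = _motif_carrier(rng, motifs[cls])
        label = int(cls)
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = int(rng.integers(spec.n_classes))
        docs.append(Document(f"syn{i:06d}", " ".join(toks), f"class{label}"))

    corpus = LabeledCorpus(docs, class_names=[f"class{c}" for c in range(spec.n_classes)])
    corpus.keyword_sets = {f"class{c}": set(kws) for c, kws in enumerate(keyword_sets)}
    corpus.char_motifs = {f"class{c}": m for c, m in enumerate(motifs)}
    return corpus


def keyword_rule_labels(corpus: LabeledCorpus,
                        keyword_sets: dict[str, set] | None = None) -> list[str]:
    """Classify each document by which class's keyword set intersects its
    tokens the most; ties go to the lexicographically first class."""
    if keyword_sets is None:
        keyword_sets = getattr(corpus, "keyword_sets", None)
    if keyword_sets is None:
        raise ValueError("corpus has no attached keyword sets; pass them explicitly")
    classes = sorted(keyword_sets)
    out = []
    for doc in corpus:
        toks = doc.text.split()
        counts = [sum(t in keyword_sets[c] for t in toks) for c in classes]
        out.append(classes[int(np.argmax(counts))])
    return out


def separability_check(corpus: LabeledCorpus,
                       keyword_sets: dict[str, set] | None = None) -> float:
    """Accuracy of the keyword-presence decision rule against the corpus
    labels.  On a noiseless strong-signal corpus this approaches 1; with
    label noise nu it approaches (1-nu) + nu/n_classes; with no keyword
    signal it sits at chance."""
    preds = keyword_rule_labels(corpus, keyword_sets)
    hits = sum(p == d.label for p, d in zip(preds, corpus))
    return hits / len(corpus)
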