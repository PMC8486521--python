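"""Reading, writing and splitting labeled text corpora.

A corpus is an ordered list of ``(doc_id, text, label)`` records with a
stable iteration order, which keeps every downstream step (vocabulary
building, splitting, encoding) reproducible.  Two on-disk layouts are
supported: a delimited file with a ``text,label`` header (comma or tab),
and one plain-text file per class with one document per line.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Document",
    "LabeledCorpus",
    "SplitSpec",
    "CorpusStats",
    "read_labeled_corpus",
    "write_delimited_corpus",
    "split_corpus",
    "split_sizes",
    "corpus_stats",
    "write_split_manifest",
]

_WS = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase and collapse runs of whitespace to single spaces."""
    return _WS.sub(" ", text.strip()).lower()


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    label: str


@dataclass
class LabeledCorpus:
    """Ordered collection of single-label documents.

    ``class_names`` is sorted lexicographically and every document label
    must appear in it; ``doc_id`` values are unique.
    """

    documents: list[Document]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = sorted({d.label for d in self.documents})
        self.validate()

    def validate(self) -> None:
        if not self.documents:
            raise ValueError("corpus is empty")
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("doc_ids are not unique")
        known = set(self.class_names)
        for d in self.documents:
            if d.label not in known:
                raise ValueError(f"label {d.label!r} not in class_names")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def labels_as_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[d.label] for d in self.documents], dtype=np.int64)

    def subset(self, indices: Sequence[int]) -> "LabeledCorpus":
        docs = [self.documents[i] for i in indices]
        return LabeledCorpus(docs, class_names=list(self.class_names))


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test proportions plus the shuffle seed."""

    train_frac: float = 0.7
    val_frac: float = 0.2
    test_frac: float = 0.1
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("each fraction must lie in (0, 1)")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


@dataclass
class CorpusStats:
    n_docs: int
    n_classes: int
    per_class: dict[str, int]
    max_len: int
    mean_len: float
    vocab_size: int


def read_labeled_corpus(path: str | Path, format: str = "delimited") -> LabeledCorpus:
    """Load a corpus from disk.

    ``format="delimited"`` expects a UTF-8 file whose header row is
    ``text<sep>label`` with the separator (comma or tab) auto-detected
    from the header.  ``format="per_class_files"`` expects a directory of
    ``<class>.txt`` files, one document per line, labels taken from the
    file stems.  Text is normalized (lowercased, whitespace collapsed) on
    the way in; blank documents are rejected with the offending line named.
    """
    path = Path(path)
    if format == "delimited":
        return _read_delimited(path)
    if format == "per_class_files":
        return _read_per_class(path)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_delimited(path: Path) -> LabeledCorpus:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8", newline="") as fh:
        header = fh.readline()
        if not header:
            raise ValueError(f"{path}: empty file")
        sep = "\t" if "\t" in header else ","
        cols = [c.strip() for c in header.rstrip("\n").split(sep)]
        if cols[:2] != ["text", "label"]:
            raise ValueError(f"{path}: header must be 'text{sep}label', got {cols!r}")
        reader = csv.reader(fh, delimiter=sep)
        docs: list[Document] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(row)}")
            text = normalize_text(row[0])
            label = row[1].strip()
            if not text:
                raise ValueError(f"{path}:{lineno}: blank text field")
            if not label:
                raise ValueError(f"{path}:{lineno}: blank label field")
            docs.append(Document(f"d{len(docs):06d}", text, label))
    if not docs:
        raise ValueError(f"{path}: corpus is empty")
    return LabeledCorpus(docs)


def _read_per_class(path: Path) -> LabeledCorpus:
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    files = sorted(path.glob("*.txt"))
    if not files:
        raise ValueError(f"{path}: no <class>.txt files found")
    docs: list[Document] = []
    for f in files:
        label = f.stem
        with open(f, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    raise ValueError(f"{f}:{lineno}: blank document line")
                docs.append(Document(f"d{len(docs):06d}", normalize_text(line), label))
    if not docs:
        raise ValueError(f"{path}: corpus is empty")
    return LabeledCorpus(docs)


def write_delimited_corpus(corpus: LabeledCorpus, path: str | Path, sep: str = "\t") -> None:
    """Write a corpus in the delimited layout (round-trips with the reader)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["text", "label"])
        for d in corpus:
            writer.writerow([d.text, d.label])


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Floor rule: |val| = floor(val_frac*n), |test| = floor(test_frac*n),
    train takes the remainder.  Reproduces the published split tables for
    totals 8472 -> (5931, 1694, 847) and 2646 -> (1853, 529, 264)."""
    n_val = math.floor(spec.val_frac * n)
    n_test = math.floor(spec.test_frac * n)
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def split_corpus(
    corpus: LabeledCorpus, spec: SplitSpec
) -> tuple[LabeledCorpus, LabeledCorpus, LabeledCorpus]:
    """Shuffle (seeded) and partition into train/val/test by the floor rule.

    With ``stratified=True`` the floor rule is applied within each class
    and the per-class remainders go to train.
    """
    n = len(corpus)
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        train_idx: list[int] = []
        val_idx: list[int] = []
        test_idx: list[int] = []
        labels = [d.label for d in corpus]
        for cls in corpus.class_names:
            cls_idx = np.array([i for i, lab in enumerate(labels) if lab == cls])
            rng.shuffle(cls_idx)
            _, n_val, n_test = split_sizes(len(cls_idx), spec)
            val_idx.extend(cls_idx[:n_val])
            test_idx.extend(cls_idx[n_val : n_val + n_test])
            train_idx.extend(cls_idx[n_val + n_test :])
        parts = (sorted(train_idx), sorted(val_idx), sorted(test_idx))
    else:
        perm = rng.permutation(n)
        _, n_val, n_test = split_sizes(n, spec)
        parts = (
            sorted(perm[n_val + n_test :].tolist()),
            sorted(perm[:n_val].tolist()),
            sorted(perm[n_val : n_val + n_test].tolist()),
        )
    train, val, test = (corpus.subset(p) for p in parts)
    for name, part in (("train", train), ("val", val), ("test", test)):
        if len(part) == 0:  # pragma: no cover - LabeledCorpus already rejects empty
            raise ValueError(f"{name} split is empty")
    return train, val, test


def corpus_stats(corpus: LabeledCorpus) -> CorpusStats:
    """Document counts, per-class counts, word-token length stats and the
    word-level vocabulary size (distinct whitespace tokens)."""
    per_class = {c: 0 for c in corpus.class_names}
    lengths = []
    vocab: set[str] = set()
    for d in corpus:
        per_class[d.label] += 1
        toks = d.text.split()
        lengths.append(len(toks))
        vocab.update(toks)
    return CorpusStats(
        n_docs=len(corpus),
        n_classes=corpus.n_classes,
        per_class=per_class,
        max_len=max(lengths),
        mean_len=float(np.mean(lengths)),
        vocab_size=len(vocab),
    )


def write_split_manifest(
    splits: Iterable[tuple[str, LabeledCorpus]], out_dir: str | Path
) -> list[Path]:
    """Write one doc-id list per split as plain text; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, part in splits:
        p = out_dir / f"{name}.ids.txt"
        p.write_text("\n".join(d.doc_id for d in part) + "\n", encoding="utf-8")
        paths.append(p)
    return paths
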