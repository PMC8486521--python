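import numpy as np
import pytest

from medtext.corpus_io import Document, LabeledCorpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_corpus():
    docs = [
        Document("d0", "tumor growth was observed", "pos"),
        Document("d1", "no invasion detected in sample", "neg"),
        Document("d2", "metastasis and tumor invasion", "pos"),
        Document("d3", "normal tissue no growth", "neg"),
    ]
    return LabeledCorpus(docs)


def random_corpus(rng, n_docs=30, n_classes=3, vocab=40, length=(3, 12)):
    words = [f"w{i}" for i in range(vocab)]
    docs = []
    for i in range(n_docs):
        n = int(rng.integers(*length))
        text = " ".join(rng.choice(words, size=n))
        docs.append(Document(f"r{i}", text, f"c{int(rng.integers(n_classes))}"))
    return LabeledCorpus(docs)
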