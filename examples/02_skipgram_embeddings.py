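"""Train skip-gram embeddings and inspect learned similarity.

Words that share windows (here the per-class keywords, which co-occur
inside documents of their class) should end up closer in cosine
similarity than words that never co-occur.
"""

import numpy as np

from medtext import SkipGramConfig, SynthSpec, cosine_similarity, generate_corpus, train_skipgram

corpus = generate_corpus(SynthSpec(n_docs=300, doc_len_range=(30, 60),
                                   keyword_rate=0.2, seed=1))
emb = train_skipgram(corpus, "word", SkipGramConfig(d=32, epochs=5, seed=0))

kw0 = sorted(corpus.keyword_sets["class0"])[:2]
kw1 = sorted(corpus.keyword_sets["class1"])[:1]
same = cosine_similarity(emb.vector(kw0[0]), emb.vector(kw0[1]))
cross = cosine_similarity(emb.vector(kw0[0]), emb.vector(kw1[0]))
print(f"epoch losses: {[round(x, 3) for x in emb.loss_history]}")
print(f"cos({kw0[0]}, {kw0[1]})  [same class] = {same:.3f}")
print(f"cos({kw0[0]}, {kw1[0]})  [other class] = {cross:.3f}")
print("-> the loss should fall across epochs and the same-class pair "
      "should score higher: both keywords appear in the same documents.")
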