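# medtext

Hybrid deep-learning text classifiers for biomedical abstracts — e.g.
assigning cancer-hallmark categories (activating invasion and metastasis,
deregulating cellular energetics, tumor-promoting inflammation) to
publication abstracts — implemented as a tested, fully seeded numpy
library with a small CLI.

## The models

Documents are encoded at two granularities: word tokens and raw
characters, each with its own skip-gram (word2vec) embedding table
trained by negative sampling (the center token predicts its window
context).

**Quad-channel hybrid LSTM (QC-LSTM).** Four parallel feature channels,
{word, char} × {convolution, LSTM}:

- per granularity, `channel(x) = conv(x) ⊕ LSTM(x)` — a text-CNN branch
  (filter widths 1/3/5, 200 feature maps, global max pooling) runs in
  parallel with an LSTM branch (`z_t = tanh(W_z[h_{t-1},x_t]+b_z)`,
  sigmoid gates `i_t, f_t, o_t`, `c_t = f_t·c_{t-1}+i_t·z_t`,
  `h_t = o_t·tanh c_t`);
- additive "hybrid" attention scores each LSTM position over the
  concatenated hidden/cell state `h_i = [h_t' ; c_t]` via
  `e_i = v_aᵀ tanh(W_r h_i + b)`, softmax-normalizes over positions, and
  forms the context `c = Σ_i w_i h_i`;
- the merged vector `h = C_out ⊕ W_out` goes through dropout and a dense
  softmax `ŷ = softmax(W h + b)`.

**Hybrid BiGRU with multihead self-attention.** Over word embeddings
only: a text-CNN branch (max **and** average pooling, concatenated) in
parallel with stacked bidirectional GRUs
(`z_t = σ(W_z[h_{t-1},x_t])`, `r_t = σ(W_r[h_{t-1},x_t])`,
`h̃_t = tanh(W[r_t⊙h_{t-1},x_t])`, `h_t=(1-z_t)h_{t-1}+z_t h̃_t`; forward
and backward states concatenated per position), then multihead
self-attention `Attention(Q,K,V) = softmax(QKᵀ/√d)V` with per-head
projections and `Q=K=V=` the BiGRU output sequence, pooled (max+avg) and
concatenated with the CNN features before dropout and the dense softmax.

Training minimizes cross-entropy (binary form for two classes,
categorical for more) with Adam / SGD / Nadam / AdaGrad; evaluation
reports accuracy, precision, recall and F1 = 2PR/(P+R) from one-vs-rest
confusion counts (macro-averaged beyond two classes).

Since the original abstract corpora are external, the package ships a
synthetic-corpus generator whose class signal can be placed at the word
level (class keywords), the character level (class motifs hidden inside
otherwise-random tokens), or both, with tunable label noise — so every
pipeline stage, including the value of the character channels, is
testable end to end.

## Worked example

`python examples/03_train_quad_channel_lstm.py` trains a scaled-down
QC-LSTM (embedding 8, hidden 6, 300 synthetic documents) and prints:

```
model parameters: 12010
train loss per epoch: [0.6902, 0.5654, 0.2506, 0.0328, 0.0015]
val accuracy per epoch: [0.55, 0.933..., 0.866..., 0.933..., 0.916...]
test metrics: accuracy 90.0%  precision 88.24%  recall 93.75%  F1 90.91%
```

The loss collapses within five epochs because the synthetic keyword
signal is strong and noiseless; the test metrics are the one-vs-rest
confusion-matrix percentages on the held-out 10% split. The other
examples cover corpus generation and separability (01), skip-gram
similarity structure (02), the attention probe of the BiGRU model (04)
and a learning-rate sweep table (05).

A CLI mirrors the pipeline for shell use:

```
medtext synth --seed 0 --out corpus.tsv
medtext prepare --corpus corpus.tsv --out-dir splits/
medtext train --corpus corpus.tsv --model qc_lstm --seed 0 --out-dir run/
medtext sweep --corpus corpus.tsv --model bigru_mha --axis learning_rate \
    --values 0.1,0.01,0.001 --seed 0 --out-dir sweep/
```

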