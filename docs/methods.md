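# Methods

## Scope and design

The package implements two hybrid architectures for single-label
document classification, their full training/evaluation pipeline, and a
synthetic-corpus generator that stands in for the external biomedical
abstract corpora the architectures were designed for. All layer
mathematics — convolution over token windows, LSTM and GRU recurrences,
additive ("hybrid") attention, scaled dot-product and multihead
attention, the dense softmax and cross-entropy — is implemented directly
on numpy. A single code path serves two purposes: called with plain
arrays the layer functions are pure forward computations checkable
against independently written scalar/loop oracles; called with tape
`Tensor` leaves they build a reverse-mode autodiff graph that the
training loop differentiates. The tape (`medtext.autodiff`) implements
only what the models need (broadcasting arithmetic, batched matmul,
gather, concat, reductions, softmax, the five activations) and its
gradients are verified against central finite differences.

## Model assembly choices

Several aspects of the architectures admit more than one reading; the
package fixes them as follows.

* **Quad channels** are {word, char} × {conv, LSTM}: per embedding
  granularity a convolution branch and an LSTM branch run in parallel
  (`channel(x) = conv(x) ⊕ LSTM(x)`), and the two granularity outputs
  are concatenated (`h = C_out ⊕ W_out`). A serial conv→LSTM stacking
  was rejected because the parallel form preserves the unpooled
  time-series information each branch needs.
* The **hybrid-attention input** is the concatenated hidden/cell state
  `h_i = [h_t' ; c_t]`, so the attention scorer sees both the exposed
  output and the memory contents.
* The **conv branches** use valid (no padding) stride-1 windows and
  global max pooling over time; the BiGRU model's CNN branch and its
  attention output are pooled by max *and* average, concatenated.
* The **BiGRU output** is the per-position concatenation of forward and
  backward states. The additive directional projection
  `g(V·A + V'·A')` sometimes written for bidirectional RNN outputs is
  absorbed into the downstream dense layer, which is an equivalent
  reparameterization and keeps the layer reusable.
* The **GRU update** is the standard convex combination
  `h_t = (1-z_t) h_{t-1} + z_t h̃_t`; the gates are bias-free, matching
  the gate equations as written.
* **Multihead attention** adds an output projection `W_O` after head
  concatenation; without it the merged width would depend on the head
  count and could not feed a fixed-width layer. Per-head key dimension
  `d = d_model / n_heads` supplies the `√d` scale. Pad-position masking
  is available (`mask_padding`) but off by default.
* **Dropout** (inverted, seeded) is applied to the merged feature vector
  immediately before the dense softmax — rates are part of the model
  configuration, placement is a package choice.
* **Loss**: for two classes the cross-entropy is exactly the binary form
  `-mean(y log p + (1-y) log(1-p))`; for more it generalizes to
  categorical `-mean(log p_y)`, since mutually exclusive classes through
  a softmax cannot use the binary form verbatim. Probabilities are
  clipped to `[1e-7, 1 - 1e-7]` before logs.
* **Metrics**: one-vs-rest confusion counts per class; with two classes
  class 1 is the positive class and the textbook formulas apply
  verbatim; with more, precision/recall are macro-averaged by default
  (micro available) and F1 is the harmonic mean of the reported pair —
  the same arithmetic that connects the published precision/recall pairs
  to their printed F1 values. Values are percentages rounded to two
  decimals. An explicit `average="macro"` is honored for binary tasks
  too (used, e.g., to characterize a majority-class predictor as 50%
  macro recall on balanced data).
* **Splitting** uses the floor rule — `|val| = floor(0.2 n)`,
  `|test| = floor(0.1 n)`, remainder to train — because it reproduces
  the published split tables for both corpus sizes (8472 → 5931/1694/847
  and 2646 → 1853/529/264) exactly. Stratified splitting applies the
  same rule per class (off by default, since the published split counts
  are not broken down per class).
* **Text normalization** is lowercasing plus whitespace collapse only;
  no stemming or stopword removal, keeping tokenization invertible.
  Tail truncation and tail padding with pad=0, unk=1.
* **Skip-gram** uses negative sampling (k = 5 by default) with noise
  distribution unigram^0.75, linear learning-rate decay, and is the only
  embedding trainer (a count-based co-occurrence method was considered
  and dropped in favor of skip-gram). Embedding matrices are copied into
  the models as trainable parameters, so pretraining is optional:
  `epochs=0` yields the seeded random initialization and the model
  fine-tunes it end to end.

## Tunable parameters

Full-size defaults follow the published configuration: filter widths
(1, 3, 5) with 200 feature maps, LSTM hidden 128, batch 512, learning
rate 0.01, Adam, dropout 0.5 (quad-channel) / 0.4 (BiGRU), ReLU
(quad-channel) / sigmoid (BiGRU) activations, 2 BiGRU layers, word
sequence length 833. Where the source configuration is silent the
package fixes: word embedding d = 100, char embedding d = 50, char
sequence length 6× the word length, 8 attention heads, hard-sigmoid
slope/intercept 0.2/0.5, optimizer moment parameters at their customary
defaults, early stopping on validation-accuracy plateau (patience 5).
Filter counts and hidden sizes are per channel.

## The synthetic generator

`SynthSpec` draws documents as uniform background tokens (random
lowercase strings, length 3–8, from a fixed background vocabulary) and
injects two independent signals: per-class keyword tokens (disjoint
sets, injected per token at `keyword_rate`) and per-class character
motifs (3–6 characters, embedded inside fresh random carrier tokens at
`char_signal_rate`). Carrier flanks are 2–4 random characters each so
carriers essentially never repeat — the motif is invisible to whole-word
encoders and detectable only at the character level. Motifs are
constructed so none contains another. Labels are re-drawn uniformly at
rate `label_noise`, so the accuracy ceiling of a perfect rule is
`(1-ν) + ν/C`; generating labels are exactly balanced (±1). Defaults
(2000 documents, 2 classes, 100–300 tokens, vocabulary 1000, 10 keywords
per class, keyword rate 0.05, char rate 0.05, no noise) describe a
moderately hard corpus of realistic document length.

What the generator does **not** emulate: topical structure, Zipfian
word frequencies, grammatical dependencies, document length extremes,
and multi-label annotation. Passing tests therefore demonstrate that the
architectures learn the kinds of signal the generator plants
(word-identity co-occurrence and sub-word motifs) under controlled
noise — not that they reach any particular accuracy on real biomedical
abstracts.

## Reduced verification configuration

Routine verification runs both models at a fixed reduced size chosen for
a single CPU: embedding 16, hidden 16, word length 64, char length 128,
16 filters of widths (1, 3, 5), 4 attention heads, 1 BiGRU layer, batch
32, learning rate 0.01 with Adam, dropout 0.2, at most 10 epochs with
plateau patience 3, on 2000 noiseless two-class synthetic documents
split 70/20/10. Under these conditions both models exceed 95% validation
accuracy within a few epochs (3-seed mean), and on a corpus whose only
signal is character motifs the quad-channel model's accuracy exceeds
both its word-channels-only ablation and chance by a wide margin —
the property the character channels exist to deliver.

## Numerical notes

* Oracle comparisons use absolute tolerance 1e-6; tape gradients match
  finite differences to ~1e-10 relative.
* Softmax subtracts the row max; sigmoid/softplus use the
  numerically stable piecewise forms.
* Argmax prediction breaks ties toward the lowest class index.
* Max-pool gradients split ties evenly among attaining positions.
* The LSTM forget-gate bias initializes to 1 (other biases 0) and
  weights are Glorot-scaled normals; these affect training speed only,
  not any oracle-checked forward semantics.
* Zero denominators in precision/recall report 0 with a logged warning;
  F1 of (0, 0) is 0 by convention.
* Degenerate inputs (empty sequences, empty pools, zero vectors in
  cosine similarity, out-of-range labels or token indices, indivisible
  head counts) raise `ValueError` rather than propagating NaNs.

## Known limitations

* Training is single-threaded numpy; the full published configuration
  (vocabulary ~29k, length 833, 200 filters, batch 512) is out of reach
  at interactive timescales, which is exactly why the reduced
  configuration and the synthetic generator exist.
* The published headline accuracies on the real corpora are not
  reproduced here: they require the external datasets and long
  stochastic runs. The package verifies the arithmetic identities those
  tables imply (F1 from precision/recall, split sizes) and the
  behavioral properties of the architectures instead.
* Gradient clipping and learning-rate schedules are not implemented;
  divergence (non-finite loss) aborts with the epoch/batch named.
* `doc_id` order, not content hashing, defines corpus identity; two
  textually equal corpora with different ids are different corpora.
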