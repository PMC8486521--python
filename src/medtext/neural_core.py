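"""Layer-level building blocks of the two hybrid classifiers.

Every operation here is a pure forward computation written against the
dual-mode primitives in :mod:`medtext.autodiff`: call it with numpy arrays
and it is plain, brute-force-checkable numpy; call it with
:class:`~medtext.autodiff.Tensor` leaves and it builds a differentiable
tape.  The recurrent cells follow the gate formulations used throughout
the text-classification literature:

* LSTM: ``z = tanh(W_z [h, x] + b_z)``, gates ``i, f, o`` sigmoid on the
  same concatenated input, ``c' = f*c + i*z``, ``h' = o * tanh(c')``.
* GRU: update/reset gates ``z, r`` sigmoid on ``[h, x]``, candidate
  ``h~ = tanh(W [r*h, x])``, ``h' = (1-z)*h + z*h~``.
* Hybrid attention: position scores ``e_i = v_a^T tanh(W_r h_i + b)``,
  softmax over positions, context = weighted sum of the ``h_i``.
* Scaled dot-product attention ``softmax(Q K^T / sqrt(d)) V`` and its
  multihead form with per-head projections plus an output projection.

Shapes are written ``[..., T, d]`` so the same code handles a single
sequence (2-D) or a batch of sequences (3-D).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import (
    Tensor,
    clip_probs,
    concatenate,
    hard_sigmoid,
    log,
    parameter,
    reduce_max,
    reduce_mean,
    reduce_sum,
    relu,
    reshape,
    sigmoid,
    softmax,
    softplus,
    swapaxes,
    tanh,
)

__all__ = [
    "ACTIVATIONS",
    "apply_activation",
    "LSTMParams",
    "LSTMState",
    "GRUParams",
    "BiGRUParams",
    "ConvFilterBank",
    "HybridAttentionParams",
    "MultiheadParams",
    "DenseParams",
    "conv1d_text",
    "pool_time",
    "lstm_step",
    "lstm_sequence",
    "gru_step",
    "gru_sequence",
    "bigru_sequence",
    "hybrid_attention",
    "scaled_dot_attention",
    "multihead_attention",
    "dense_softmax",
    "cross_entropy_loss",
    "save_params",
    "load_params",
]

ACTIVATIONS = {
    "relu": relu,
    "sigmoid": sigmoid,
    "softplus": softplus,
    "hard_sigmoid": hard_sigmoid,
    "tanh": tanh,
    "linear": lambda z: z,
}


def apply_activation(name: str, z):
    """Elementwise activation by name (relu / sigmoid / softplus /
    hard_sigmoid / tanh / linear)."""
    try:
        fn = ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")
    return fn(z)


def _linear(x, W, b=None):
    """x @ W^T (+ b) where W has shape [out, in]."""
    y = x @ swapaxes(W, -1, -2)
    return y if b is None else y + b


def _shape(x):
    return x.data.shape if isinstance(x, Tensor) else np.asarray(x).shape


# ---------------------------------------------------------------------------
# convolution over token positions
# ---------------------------------------------------------------------------


@dataclass
class ConvFilterBank:
    """One set of convolution kernels per filter width.

    ``kernels[h]`` has shape [n_filters, h, d]; ``biases[h]`` shape
    [n_filters].  Valid (no-padding) stride-1 windows, so a width-``h``
    filter over ``n`` positions yields a feature map of length n-h+1.
    """

    kernels: dict[int, object]
    biases: dict[int, object]
    activation: str = "relu"

    @property
    def widths(self) -> list[int]:
        return sorted(self.kernels)

    @classmethod
    def init(cls, rng: np.random.Generator, widths: Sequence[int], n_filters: int,
             d: int, activation: str = "relu", trainable: bool = True):
        kernels, biases = {}, {}
        for h in widths:
            scale = np.sqrt(2.0 / (h * d + n_filters))
            k = rng.normal(0.0, scale, size=(n_filters, h, d))
            b = np.zeros(n_filters)
            kernels[h] = Tensor(k, requires_grad=True) if trainable else k
            biases[h] = Tensor(b, requires_grad=True) if trainable else b
        return cls(kernels=kernels, biases=biases, activation=activation)

    def params(self) -> list[Tensor]:
        return [v for h in self.widths for v in (self.kernels[h], self.biases[h])]


def conv1d_text(X, bank: ConvFilterBank):
    """Text convolution: for each width h, slide every filter over the
    embedded sequence X [..., n, d] and return a feature map
    [..., n-h+1, n_filters] per width (activation applied)."""
    n, d = _shape(X)[-2], _shape(X)[-1]
    maps = []
    for h in bank.widths:
        if n < h:
            raise ValueError(f"sequence length {n} shorter than filter width {h}")
        L = n - h + 1
        # windows [..., L, h*d]: concatenate the h shifted views on the last axis
        windows = concatenate([X[..., j : j + L, :] for j in range(h)], axis=-1)
        kern = bank.kernels[h]
        W = reshape(kern, (_shape(kern)[0], h * d))  # [F, h*d]
        t = _linear(windows, W, bank.biases[h])
        maps.append(apply_activation(bank.activation, t))
    return maps


def pool_time(maps, mode: str = "max"):
    """Pool each feature map over its time axis, one value per filter;
    maps may be a single array [..., L, F] or a list of them (results are
    concatenated on the filter axis)."""
    if isinstance(maps, (list, tuple)):
        return concatenate([pool_time(m, mode) for m in maps], axis=-1)
    L = _shape(maps)[-2]
    if L == 0:
        raise ValueError("cannot pool an empty feature map")
    if mode == "max":
        return reduce_max(maps, axis=-2)
    if mode == "avg":
        return reduce_mean(maps, axis=-2)
    raise ValueError(f"unknown pooling mode {mode!r}")


# ---------------------------------------------------------------------------
# recurrent cells
# ---------------------------------------------------------------------------


@dataclass
class LSTMParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t]; all four
    weight matrices share the shape [hidden, hidden + input_dim]."""

    W_z: object
    W_i: object
    W_f: object
    W_o: object
    b_z: object
    b_i: object
    b_f: object
    b_o: object
    hidden: int

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, hidden: int,
             trainable: bool = True):
        def w():
            m = rng.normal(0.0, np.sqrt(2.0 / (hidden + input_dim + hidden)),
                           size=(hidden, hidden + input_dim))
            return Tensor(m, requires_grad=True) if trainable else m

        def b(init=0.0):
            v = np.full(hidden, init, dtype=float)
            return Tensor(v, requires_grad=True) if trainable else v

        # forget-gate bias starts at 1: standard trick to keep memory early on
        return cls(W_z=w(), W_i=w(), W_f=w(), W_o=w(),
                   b_z=b(), b_i=b(), b_f=b(1.0), b_o=b(), hidden=hidden)

    def params(self) -> list[Tensor]:
        return [self.W_z, self.W_i, self.W_f, self.W_o,
                self.b_z, self.b_i, self.b_f, self.b_o]


@dataclass
class LSTMState:
    h: object
    c: object

    @classmethod
    def zeros(cls, hidden: int, batch_shape: tuple[int, ...] = ()):
        z = np.zeros(batch_shape + (hidden,))
        return cls(h=z, c=z.copy())


def lstm_step(x_t, state: LSTMState, params: LSTMParams) -> LSTMState:
    """One LSTM update: candidate z (tanh), gates i/f/o (sigmoid),
    c' = f*c + i*z, h' = o * tanh(c')."""
    if _shape(x_t)[-1] + _shape(state.h)[-1] != _shape(params.W_z)[-1]:
        raise ValueError("lstm_step: input/hidden dims do not match W_z columns")
    hx = concatenate([state.h, x_t], axis=-1)
    z = tanh(_linear(hx, params.W_z, params.b_z))
    i = sigmoid(_linear(hx, params.W_i, params.b_i))
    f = sigmoid(_linear(hx, params.W_f, params.b_f))
    o = sigmoid(_linear(hx, params.W_o, params.b_o))
    c_new = f * state.c + i * z
    h_new = o * tanh(c_new)
    return LSTMState(h=h_new, c=c_new)


def _stack_time(steps):
    """Stack per-step [..., H] results into [..., T, H]."""
    cols = []
    for s in steps:
        sh = _shape(s)
        cols.append(reshape(s, sh[:-1] + (1, sh[-1])))
    return concatenate(cols, axis=-2)


def lstm_sequence(X, params: LSTMParams, init: LSTMState | None = None,
                  return_cells: bool = False):
    """Run the LSTM over X [..., T, d]; returns (outputs [..., T, hidden],
    final state).  With ``return_cells`` the per-step cell states are
    stacked too (the hybrid-attention input needs them)."""
    T = _shape(X)[-2]
    if T == 0:
        raise ValueError("lstm_sequence: empty sequence")
    if init is None:
        init = LSTMState.zeros(params.hidden, _shape(X)[:-2])
    state = init
    hs, cs = [], []
    for t in range(T):
        state = lstm_step(X[..., t, :], state, params)
        hs.append(state.h)
        if return_cells:
            cs.append(state.c)
    outputs = _stack_time(hs)
    if return_cells:
        return outputs, _stack_time(cs), state
    return outputs, state


@dataclass
class GRUParams:
    """Update/reset/candidate weights on the concatenated [h_{t-1}, x_t]
    (bias-free, matching the gate equations used here)."""

    W_z: object
    W_r: object
    W: object
    hidden: int

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, hidden: int,
             trainable: bool = True):
        def w():
            m = rng.normal(0.0, np.sqrt(2.0 / (hidden + input_dim + hidden)),
                           size=(hidden, hidden + input_dim))
            return Tensor(m, requires_grad=True) if trainable else m

        return cls(W_z=w(), W_r=w(), W=w(), hidden=hidden)

    def params(self) -> list[Tensor]:
        return [self.W_z, self.W_r, self.W]


def gru_step(x_t, h_prev, params: GRUParams):
    """One GRU update: h' = (1-z)*h_prev + z*h~ with
    h~ = tanh(W [r*h_prev, x])."""
    if _shape(x_t)[-1] + _shape(h_prev)[-1] != _shape(params.W_z)[-1]:
        raise ValueError("gru_step: input/hidden dims do not match W_z columns")
    hx = concatenate([h_prev, x_t], axis=-1)
    z = sigmoid(_linear(hx, params.W_z))
    r = sigmoid(_linear(hx, params.W_r))
    cand = tanh(_linear(concatenate([r * h_prev, x_t], axis=-1), params.W))
    return (1.0 - z) * h_prev + z * cand


def gru_sequence(X, params: GRUParams, h0=None):
    """Unidirectional GRU over X [..., T, d] -> outputs [..., T, hidden]."""
    T = _shape(X)[-2]
    if T == 0:
        raise ValueError("gru_sequence: empty sequence")
    h = np.zeros(_shape(X)[:-2] + (params.hidden,)) if h0 is None else h0
    hs = []
    for t in range(T):
        h = gru_step(X[..., t, :], h, params)
        hs.append(h)
    return _stack_time(hs)


@dataclass
class BiGRUParams:
    forward: GRUParams
    backward: GRUParams

    def __post_init__(self) -> None:
        if self.forward.hidden != self.backward.hidden:
            raise ValueError("forward/backward hidden sizes differ")

    @property
    def hidden(self) -> int:
        return self.forward.hidden

    @classmethod
    def init(cls, rng: np.random.Generator, input_dim: int, hidden: int,
             trainable: bool = True):
        return cls(forward=GRUParams.init(rng, input_dim, hidden, trainable),
                   backward=GRUParams.init(rng, input_dim, hidden, trainable))

    def params(self) -> list[Tensor]:
        return self.forward.params() + self.backward.params()


def bigru_sequence(X, params: BiGRUParams):
    """Bidirectional GRU: forward pass over X, backward pass over the
    reversed sequence re-reversed into input order; output row t is the
    concatenation [forward_state_t ; backward_state_t], shape
    [..., T, 2*hidden]."""
    fwd = gru_sequence(X, params.forward)
    bwd_rev = gru_sequence(X[..., ::-1, :], params.backward)
    bwd = bwd_rev[..., ::-1, :]
    return concatenate([fwd, bwd], axis=-1)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------


@dataclass
class HybridAttentionParams:
    """Score projection W_r [k, m], score vector v_a [k], bias b [k]."""

    W_r: object
    v_a: object
    b: object

    @classmethod
    def init(cls, rng: np.random.Generator, m: int, k: int | None = None,
             trainable: bool = True):
        k = m if k is None else k

        def mk(shape, scale):
            a = rng.normal(0.0, scale, size=shape)
            return Tensor(a, requires_grad=True) if trainable else a

        return cls(W_r=mk((k, m), np.sqrt(2.0 / (k + m))),
                   v_a=mk((k,), 1.0 / np.sqrt(k)),
                   b=mk((k,), 0.0) if trainable else np.zeros(k))

    def params(self) -> list[Tensor]:
        return [self.W_r, self.v_a, self.b]


def hybrid_attention(H, params: HybridAttentionParams, return_weights: bool = False):
    """Additive position attention over H [..., T, m]: scores
    e_i = v_a^T tanh(W_r h_i + b), weights = softmax over positions,
    context = sum_i w_i h_i, shape [..., m]."""
    T = _shape(H)[-2]
    if T == 0:
        raise ValueError("hybrid_attention: empty sequence")
    k = _shape(params.v_a)[-1]
    proj = tanh(_linear(H, params.W_r, params.b))          # [..., T, k]
    va = reshape(params.v_a, (k, 1))
    e = proj @ va                                          # [..., T, 1]
    w = softmax(e, axis=-2)
    context = reduce_sum(w * H, axis=-2)                   # [..., m]
    if return_weights:
        w_flat = reshape(w, _shape(w)[:-1])
        return context, w_flat
    return context


def scaled_dot_attention(Q, K, V, key_mask=None, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d)) V for Q, K, V shaped [..., n, d].

    ``key_mask`` (optional, [..., n] with 1=attend / 0=ignore) pushes the
    scores of masked key positions to -inf before the softmax, e.g. to
    hide padding.
    """
    d = _shape(Q)[-1]
    if d == 0:
        raise ValueError("scaled_dot_attention: zero key dimension")
    scores = (Q @ swapaxes(K, -1, -2)) * (1.0 / np.sqrt(d))
    if key_mask is not None:
        bias = (1.0 - np.asarray(key_mask, dtype=float)) * -1e9
        scores = scores + bias[..., None, :]
    A = softmax(scores, axis=-1)
    out = A @ V
    return (out, A) if return_weights else out


@dataclass
class MultiheadParams:
    """Per-head projections W_q/W_k/W_v (each [d_model, d_head]) and the
    output projection W_o [n_heads*d_head, d_model] that merges heads."""

    W_q: list
    W_k: list
    W_v: list
    W_o: object

    @property
    def n_heads(self) -> int:
        return len(self.W_q)

    @classmethod
    def init(cls, rng: np.random.Generator, d_model: int, n_heads: int,
             trainable: bool = True):
        if d_model % n_heads != 0:
            raise ValueError(f"model dim {d_model} not divisible by {n_heads} heads")
        d_head = d_model // n_heads

        def mk(shape):
            a = rng.normal(0.0, np.sqrt(2.0 / sum(shape)), size=shape)
            return Tensor(a, requires_grad=True) if trainable else a

        return cls(W_q=[mk((d_model, d_head)) for _ in range(n_heads)],
                   W_k=[mk((d_model, d_head)) for _ in range(n_heads)],
                   W_v=[mk((d_model, d_head)) for _ in range(n_heads)],
                   W_o=mk((n_heads * d_head, d_model)))

    @classmethod
    def identity(cls, d_model: int):
        """Single head with identity projections; reduces multihead
        attention to plain scaled dot-product attention."""
        eye = np.eye(d_model)
        return cls(W_q=[eye], W_k=[eye], W_v=[eye], W_o=np.eye(d_model))

    def params(self) -> list[Tensor]:
        return list(self.W_q) + list(self.W_k) + list(self.W_v) + [self.W_o]


def multihead_attention(Q, K, V, params: MultiheadParams, key_mask=None,
                        return_weights: bool = False):
    """Multihead attention: project Q/K/V per head, run scaled dot-product
    attention with the per-head key dimension, concatenate the head
    outputs and apply the output projection."""
    heads, weights = [], []
    for Wq, Wk, Wv in zip(params.W_q, params.W_k, params.W_v):
        out = scaled_dot_attention(Q @ Wq, K @ Wk, V @ Wv, key_mask=key_mask,
                                   return_weights=return_weights)
        if return_weights:
            out, A = out
            weights.append(A)
        heads.append(out)
    merged = concatenate(heads, axis=-1) @ params.W_o
    return (merged, weights) if return_weights else merged


# ---------------------------------------------------------------------------
# output layer and loss
# ---------------------------------------------------------------------------


@dataclass
class DenseParams:
    """Fully connected layer [n_classes, in_dim] + bias feeding softmax."""

    W: object
    b: object

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, n_classes: int,
             trainable: bool = True):
        W = rng.normal(0.0, np.sqrt(2.0 / (in_dim + n_classes)),
                       size=(n_classes, in_dim))
        b = np.zeros(n_classes)
        if trainable:
            return cls(W=Tensor(W, requires_grad=True), b=Tensor(b, requires_grad=True))
        return cls(W=W, b=b)

    def params(self) -> list[Tensor]:
        return [self.W, self.b]


def dense_softmax(h, params: DenseParams):
    """softmax(W h + b): class probabilities, positive and summing to 1."""
    if _shape(h)[-1] != _shape(params.W)[-1]:
        raise ValueError("dense_softmax: input dim does not match weight columns")
    return softmax(_linear(h, params.W, params.b), axis=-1)


def cross_entropy_loss(p, y, eps: float = 1e-7):
    """Mean cross-entropy of predicted class probabilities p [N, C]
    against integer labels y [N].

    For two classes this is exactly the binary form
    -mean(y log p1 + (1-y) log(1-p1)) because the softmax rows sum to 1;
    for C > 2 it is the categorical generalization -mean(log p[y]).
    Probabilities are clipped to [eps, 1-eps] before the log.
    """
    y = np.asarray(y, dtype=np.int64)
    C = _shape(p)[-1]
    if y.min() < 0 or y.max() >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    N = y.shape[0]
    p_true = clip_probs(p, eps)[np.arange(N), y]
    return -reduce_mean(log(p_true))


# ---------------------------------------------------------------------------
# parameter serialization: flat named arrays + a JSON manifest
# ---------------------------------------------------------------------------


def save_params(named: dict[str, object], path: str | Path) -> None:
    """Save a flat name -> array bundle as <path>.npz with a JSON manifest
    <path>.json recording name, shape and dtype of each entry."""
    path = Path(path)
    arrays = {k: (v.data if isinstance(v, Tensor) else np.asarray(v))
              for k, v in named.items()}
    np.savez(path.with_suffix(".npz"), **arrays)
    manifest = {k: {"shape": list(a.shape), "dtype": str(a.dtype)}
                for k, a in arrays.items()}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_params(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        out = {k: z[k] for k in z.files}
    for k, meta in manifest.items():
        if list(out[k].shape) != meta["shape"]:
            raise ValueError(f"manifest/array shape mismatch for {k!r}")
    return out
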