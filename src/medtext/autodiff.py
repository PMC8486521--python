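"""Minimal reverse-mode automatic differentiation on numpy arrays.

The layer math in :mod:`medtext.neural_core` is written against a small set
of primitives (``tanh``, ``sigmoid``, ``matmul`` via ``@``, ``concatenate``,
``softmax``, ...) that accept either a plain :class:`numpy.ndarray` or a
:class:`Tensor`.  Called with arrays the functions are ordinary numpy and
can be checked against brute-force oracles; called with tensors they build
a tape that :meth:`Tensor.backward` differentiates, which is what the
training loop uses.

Only what the two classifiers need is implemented: broadcasting
elementwise arithmetic, batched matmul on operands of ndim >= 2, gather
(``__getitem__`` with slices or integer arrays), concatenate, swapaxes,
reshape, reductions (sum / mean / max), softmax, log, exp and the five
activation functions.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "tanh",
    "sigmoid",
    "relu",
    "softplus",
    "hard_sigmoid",
    "exp",
    "log",
    "softmax",
    "reduce_sum",
    "reduce_mean",
    "reduce_max",
    "concatenate",
    "swapaxes",
    "reshape",
    "clip_probs",
    "gradient_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_priority__ = 1000

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = parents
        self._backward = backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        out._backward = lambda g: (self._accum(g), other._accum(g))
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g * other.data),
            other._accum(g * self.data),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        out._backward = lambda g: (
            self._accum(g / other.data),
            other._accum(-g * self.data / other.data**2),
        )
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self.data, other.data
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("tape matmul requires operands of ndim >= 2")
        out = Tensor(a @ b, parents=(self, other))

        def back(g):
            self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return _as_tensor(other) @ self

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = back
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable leaf.  With ``rng`` given, ``data`` is a shape tuple and
    the leaf is Glorot-style initialized: N(0, scale) with
    scale = sqrt(2 / (fan_in + fan_out)) unless overridden."""
    if rng is not None:
        shape = tuple(data)
        if scale is None:
            fan_in = shape[-1] if len(shape) >= 1 else 1
            fan_out = shape[0] if len(shape) >= 2 else 1
            scale = np.sqrt(2.0 / (fan_in + fan_out))
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


# ---------------------------------------------------------------------------
# dual-mode primitives (ndarray in -> ndarray out; Tensor in -> Tensor out)
# ---------------------------------------------------------------------------

def _unary(x, fwd, dfwd):
    if isinstance(x, Tensor):
        y = fwd(x.data)
        out = Tensor(y, parents=(x,))
        out._backward = lambda g: x._accum(g * dfwd(x.data, y))
        return out
    return fwd(np.asarray(x, dtype=np.float64))


def tanh(x):
    return _unary(x, np.tanh, lambda xd, y: 1.0 - y**2)


def sigmoid(x):
    def fwd(xd):
        out = np.empty_like(xd)
        pos = xd >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
        e = np.exp(xd[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    return _unary(x, fwd, lambda xd, y: y * (1.0 - y))


def relu(x):
    return _unary(x, lambda xd: np.maximum(xd, 0.0), lambda xd, y: (xd > 0).astype(float))


def softplus(x):
    # ln(1 + e^x), computed stably as max(x, 0) + log1p(exp(-|x|))
    def fwd(xd):
        return np.maximum(xd, 0.0) + np.log1p(np.exp(-np.abs(xd)))

    return _unary(x, fwd, lambda xd, y: _sigmoid_np(xd))


def hard_sigmoid(x):
    # clip(0.2 x + 0.5, 0, 1)
    def fwd(xd):
        return np.clip(0.2 * xd + 0.5, 0.0, 1.0)

    def dfwd(xd, y):
        return np.where((xd > -2.5) & (xd < 2.5), 0.2, 0.0)

    return _unary(x, fwd, dfwd)


def _sigmoid_np(xd):
    out = np.empty_like(xd)
    pos = xd >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-xd[pos]))
    e = np.exp(xd[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def exp(x):
    return _unary(x, np.exp, lambda xd, y: y)


def log(x):
    return _unary(x, np.log, lambda xd, y: 1.0 / xd)


def softmax(x, axis: int = -1):
    """Numerically stable softmax along ``axis``."""

    def fwd(xd):
        z = xd - xd.max(axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)

    if isinstance(x, Tensor):
        y = fwd(x.data)
        out = Tensor(y, parents=(x,))

        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

        out._backward = back
        return out
    return fwd(np.asarray(x, dtype=np.float64))


def reduce_sum(x, axis=None, keepdims: bool = False):
    if isinstance(x, Tensor):
        out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(np.broadcast_to(g, x.data.shape))

        out._backward = back
        return out
    return np.asarray(x).sum(axis=axis, keepdims=keepdims)


def reduce_mean(x, axis=None, keepdims: bool = False):
    if isinstance(x, Tensor):
        n = x.data.size if axis is None else x.data.shape[axis]
        return reduce_sum(x, axis=axis, keepdims=keepdims) * (1.0 / n)
    return np.asarray(x).mean(axis=axis, keepdims=keepdims)


def reduce_max(x, axis: int, keepdims: bool = False):
    """Max over one axis; the gradient flows to the (first) argmax."""
    if isinstance(x, Tensor):
        y = x.data.max(axis=axis, keepdims=True)
        mask = (x.data == y).astype(float)
        mask /= mask.sum(axis=axis, keepdims=True)  # split ties evenly
        out = Tensor(y if keepdims else np.squeeze(y, axis=axis), parents=(x,))

        def back(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            x._accum(mask * g)

        out._backward = back
        return out
    return np.asarray(x).max(axis=axis, keepdims=keepdims)


def concatenate(xs: Sequence, axis: int = -1):
    if _is_tensor(*xs):
        ts = [_as_tensor(x) for x in xs]
        out = Tensor(np.concatenate([t.data for t in ts], axis=axis), parents=tuple(ts))
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)

        def back(g):
            for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

        out._backward = back
        return out
    return np.concatenate([np.asarray(x) for x in xs], axis=axis)


def swapaxes(x, a: int, b: int):
    if isinstance(x, Tensor):
        out = Tensor(np.swapaxes(x.data, a, b), parents=(x,))
        out._backward = lambda g: x._accum(np.swapaxes(g, a, b))
        return out
    return np.swapaxes(np.asarray(x), a, b)


def reshape(x, shape):
    if isinstance(x, Tensor):
        out = Tensor(x.data.reshape(shape), parents=(x,))
        out._backward = lambda g: x._accum(g.reshape(x.data.shape))
        return out
    return np.asarray(x).reshape(shape)


def clip_probs(x, eps: float = 1e-7):
    """Clip probabilities into [eps, 1-eps]; gradient passes only where
    the value was not clipped."""
    if isinstance(x, Tensor):
        y = np.clip(x.data, eps, 1.0 - eps)
        out = Tensor(y, parents=(x,))
        inside = ((x.data > eps) & (x.data < 1.0 - eps)).astype(float)
        out._backward = lambda g: x._accum(g * inside)
        return out
    return np.clip(np.asarray(x, dtype=np.float64), eps, 1.0 - eps)


def gradient_check(fn, params: Iterable[Tensor], h: float = 1e-6) -> float:
    """Max relative error between tape gradients of scalar ``fn()`` and
    central finite differences over every entry of ``params``."""
    params = list(params)
    for p in params:
        p.zero_grad()
    out = fn()
    out.backward()
    worst = 0.0
    for p in params:
        g = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            f_hi = float(fn().data)
            flat[i] = orig - h
            f_lo = float(fn().data)
            flat[i] = orig
            num = (f_hi - f_lo) / (2 * h)
            denom = max(1.0, abs(num), abs(g.ravel()[i]))
            worst = max(worst, abs(num - g.ravel()[i]) / denom)
    return worst
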