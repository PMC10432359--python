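"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerics layer for the surrogate predictor and the candidate
drug-response models: dense tensors, a tape built as operations execute, and
a topological-order backward pass. Graph operations (neighborhood
aggregation, pooling) are expressed with gather / segment primitives over a
flat node matrix, so a batch of graphs is a single block matrix plus integer
index vectors — the usual disjoint-union batching for message passing.

Everything is float64 and seeded explicitly; given identical inputs and
seeds, training runs are bitwise reproducible.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "parameter", "gather_rows", "segment_sum", "segment_mean",
    "segment_max", "concat", "smooth_l1", "SGD", "Adam", "glorot",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient back down to the shape it was broadcast from."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * s * (1 - s))

        out._backward = bwd
        return out

    def softplus(self):
        x = self.data
        val = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))
        out = Tensor(val, parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * sig)

        out._backward = bwd
        return out

    def prelu(self, slope: "Tensor"):
        """PReLU with a learnable scalar slope for the negative part."""
        s = float(slope.data.reshape(-1)[0])
        pos = self.data >= 0
        out = Tensor(np.where(pos, self.data, s * self.data), parents=(self, slope))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, s))
            if slope.requires_grad:
                slope._accumulate(
                    np.array([(g * np.where(pos, 0.0, self.data)).sum()]).reshape(
                        slope.shape
                    )
                )

        out._backward = bwd
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions & shaping --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bwd
        return out


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           scale: float = 1.0) -> Tensor:
    """Glorot-uniform weight matrix (fan_in x fan_out), optionally rescaled."""
    limit = scale * np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=(fan_in, fan_out)))


# -- structured ops ------------------------------------------------------------


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(t.data[idx], parents=(t,))

    def bwd(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = bwd
    return out


def segment_sum(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-add: out[s] = sum of rows of t with segment id s."""
    segments = np.asarray(segments, dtype=np.int64)
    data = np.zeros((num_segments,) + t.shape[1:])
    np.add.at(data, segments, t.data)
    out = Tensor(data, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            t._accumulate(g[segments])

    out._backward = bwd
    return out


def segment_mean(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    segments = np.asarray(segments, dtype=np.int64)
    counts = np.bincount(segments, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0).reshape((-1,) + (1,) * (t.data.ndim - 1))
    return segment_sum(t, segments, num_segments) * Tensor(1.0 / counts)


def segment_max(t: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-max; empty segments yield 0. Gradient is routed to
    every row attaining the maximum (deterministic)."""
    segments = np.asarray(segments, dtype=np.int64)
    data = np.full((num_segments,) + t.shape[1:], -np.inf)
    np.maximum.at(data, segments, t.data)
    empty = ~np.isfinite(data)
    data = np.where(empty, 0.0, data)
    out = Tensor(data, parents=(t,))

    def bwd(g):
        if t.requires_grad:
            mask = (t.data == data[segments]).astype(np.float64)
            t._accumulate(g[segments] * mask)

    out._backward = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out


def smooth_l1(pred: Tensor, truth: np.ndarray, beta: float = 1.0) -> Tensor:
    """Batch smooth-L1 objective: mean over elements of the piecewise loss
    0.5 e^2 / beta when |e| < beta, |e| - 0.5 beta otherwise (e = truth - pred).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    truth = np.asarray(truth, dtype=np.float64)
    e = pred.data - truth
    per = np.where(np.abs(e) < beta, 0.5 * e**2 / beta, np.abs(e) - 0.5 * beta)
    out = Tensor(per.mean(), parents=(pred,))

    def bwd(g):
        if pred.requires_grad:
            d = np.where(np.abs(e) < beta, e / beta, np.sign(e))
            pred._accumulate(g * d / e.size)

    out._backward = bwd
    return out


# -- optimizers ----------------------------------------------------------------


class SGD:
    """Plain stochastic gradient descent with L2 weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            p.data -= self.lr * g


class Adam:
    """Adam with additive L2 regularization (decay folded into the gradient)."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
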