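"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the message-passing network: a small
tape-based autodiff engine providing exactly the operations graph neural
networks need — dense linear algebra, pointwise nonlinearities, row gather
and segment (scatter-add) reductions for variable-size graphs — plus the
AdamW optimizer.  Gradients are accumulated reverse-mode through a
topologically sorted tape; correctness is established by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "MLP", "AdamW",
           "concat", "gather_rows", "segment_sum", "segment_softmax", "rms_norm"]


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def bw(g):
            self._accum(g)
            other._accum(g)
        out._backward = bw
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
        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bw
        return out

    # -- nonlinearities and reductions -------------------------------------

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y ** 2))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / np.maximum(y, 1e-300))
        return out

    def abs(self):
        s = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * s)
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self):
        return self.sum() / float(self.data.size)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            p._accum(g[tuple(sl)])
    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor; gradient scatter-adds back."""
    out = Tensor(x.data[index], parents=(x,))
    def bw(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, index, g)
        x._accum(acc)
    out._backward = bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets; gradient is a gather."""
    acc = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(acc, segment_ids, x.data)
    out = Tensor(acc, parents=(x,))
    out._backward = lambda g: x._accum(g[segment_ids])
    return out


def rms_norm(x: Tensor, eps: float = 1e-8) -> Tensor:
    """Row-wise RMS normalization (no learned gain)."""
    d = x.data.shape[1]
    ms = (x * x).sum(axis=1, keepdims=True) * (1.0 / d)
    return x / (ms + eps).sqrt()


def segment_softmax(scores: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a (N, k) score tensor normalized within each segment.

    The per-segment max is treated as a constant shift (standard stabilized
    softmax), which leaves gradients exact.
    """
    shift = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(shift, segment_ids, scores.data)
    e = (scores - Tensor(shift[segment_ids])).exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e / gather_rows(denom, segment_ids)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Linear:
    """Affine layer with fan-in uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Parameter(rng.uniform(-bound, bound, size=(n_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class MLP:
    """Stack of Linear layers with tanh between (none after the last)."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]


class AdamW:
    """AdamW: Adam with decoupled weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
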