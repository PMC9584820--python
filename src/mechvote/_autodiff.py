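"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains two small neural networks (an LSTM contribution policy and
a two-stage graph network) whose objectives require exact gradients through
the game's payout arithmetic.  This module provides the needed subset of
reverse-mode AD: a ``Tensor`` wrapping a float64 ``ndarray``, broadcasting
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
indexing, concatenation and numerically stable log-softmax.

Graphs are only recorded when a participating tensor has ``requires_grad``
set, so the same forward code doubles as a plain-numpy fast path during
rollouts that need no gradient.  ``backward`` runs an iterative topological
sort (no recursion-depth limit).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "parameter",
    "constant",
    "stop_grad",
    "concat",
    "tanh",
    "sigmoid",
    "exp",
    "log",
    "log_softmax",
    "softmax",
]


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph recording (rollout fast path)."""

    def __enter__(self):
        self._saved = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._saved
        return False


def _track(*tensors) -> bool:
    return _GRAD_ENABLED[0] and any(t.requires_grad for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 array node in a reverse-mode computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bwd=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._bwd = _bwd

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` into every ancestor's ``.grad``."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        if not _track(self):
            return Tensor(-self.data)

        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, True, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor(out_data, True, (self, other), bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        if not isinstance(p, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**p
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor(out_data, True, (self,), bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        if not _track(self, other):
            return Tensor(out_data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor(out_data, True, (self, other), bwd)

    def __rmatmul__(self, other):
        return _as_tensor(other) @ self

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor(out_data, True, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(out_data, True, (self,), bwd)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not _track(self):
            return Tensor(out_data)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, True, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng=None) -> Tensor:
    """A leaf tensor with gradient tracking enabled."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def stop_grad(x: Tensor) -> Tensor:
    """Detach ``x`` from the graph (the ⊥ operation of SCG estimators)."""
    return Tensor(x.data.copy())


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _track(*tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(out_data, True, tuple(tensors), bwd)


def tanh(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.tanh(x.data)
    if not _track(x):
        return Tensor(out_data)

    def bwd(g):
        x._accum(g * (1.0 - out_data**2))

    return Tensor(out_data, True, (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    if not _track(x):
        return Tensor(out_data)

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, True, (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.exp(x.data)
    if not _track(x):
        return Tensor(out_data)

    def bwd(g):
        x._accum(g * out_data)

    return Tensor(out_data, True, (x,), bwd)


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.log(x.data)
    if not _track(x):
        return Tensor(out_data)

    def bwd(g):
        x._accum(g / x.data)

    return Tensor(out_data, True, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (max-shift is a constant, so exact)."""
    x = _as_tensor(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    lse = log(exp(z).sum(axis=axis, keepdims=True))
    return z - lse


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))
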