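"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order, accumulating gradients.  Only the primitives the event
extraction models need are provided (elementwise arithmetic, matmul, tanh,
sigmoid, exp, log, reductions, concatenation, slicing), all with full
broadcasting support.  Everything runs in float64 so analytic gradients can
be verified against central differences to tight tolerances.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: tuple["Tensor", ...] = (),
        _backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = _prev if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- niceties ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(_unbroadcast(-g, self.shape))

        out._backward = backward if out.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = backward if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = backward if out.requires_grad else None
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accum(_matmul_grad_left(g, self.data, other.data))
            if other.requires_grad:
                other._accum(_matmul_grad_right(g, self.data, other.data))

        out._backward = backward if out.requires_grad else None
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g * (1.0 - y * y))

        out._backward = backward if out.requires_grad else None
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g * y * (1.0 - y))

        out._backward = backward if out.requires_grad else None
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g * y)

        out._backward = backward if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g / self.data)

        out._backward = backward if out.requires_grad else None
        return out

    # -- reductions & shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def backward(g: Array) -> None:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        out._backward = backward if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g.reshape(self.shape))

        out._backward = backward if out.requires_grad else None
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _prev=(self,))

        def backward(g: Array) -> None:
            self._accum(g.T)

        out._backward = backward if out.requires_grad else None
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def backward(g: Array) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = backward if out.requires_grad else None
        return out

    # -- autodiff ---------------------------------------------------------

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _matmul_grad_left(g: Array, a: Array, b: Array) -> Array:
    if b.ndim == 1 and a.ndim == 1:
        return g * b
    if b.ndim == 1:
        return np.outer(g, b) if g.ndim == 1 else g[..., None] * b
    if a.ndim == 1:
        return g @ b.T
    return _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)


def _matmul_grad_right(g: Array, a: Array, b: Array) -> Array:
    if a.ndim == 1 and b.ndim == 1:
        return g * a
    if a.ndim == 1:
        return np.outer(a, g) if g.ndim == 1 else a[:, None] @ g[None, ...]
    if b.ndim == 1:
        return np.swapaxes(a, -1, -2) @ g
    return _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _prev=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = backward if out.requires_grad else None
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def backward(g: Array) -> None:
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    out._backward = backward if out.requires_grad else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtracted before exponentiation)."""
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(probs: Tensor, onehot: Array) -> Tensor:
    """L = -sum_i sum_j t_ij log p_ij over instances i and classes j.

    Since t is one-hot, only the gold-class probability enters each term;
    selecting it before the log keeps the loss finite (0) at certainty.
    """
    gold = (as_tensor(onehot) * probs).sum(axis=-1)
    return -gold.log().sum()


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def collect_parameters(obj) -> list[Tensor]:
    """Flatten nested dicts/lists/tuples of Tensors into a parameter list."""
    out: list[Tensor] = []

    def rec(o) -> None:
        if isinstance(o, Tensor):
            if o.requires_grad:
                out.append(o)
        elif isinstance(o, dict):
            for v in o.values():
                rec(v)
        elif isinstance(o, (list, tuple)):
            for v in o:
                rec(v)

    rec(obj)
    return out


def numerical_gradient(
    f: Callable[[], Tensor], params: Iterable[Tensor], eps: float = 1e-6
) -> list[Array]:
    """Central-difference gradients of a scalar-valued closure, for checks."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(f().data)
            flat[i] = orig - eps
            lo = float(f().data)
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads
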