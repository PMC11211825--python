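"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps a
float64 ``ndarray`` and records the operation that produced it. Calling
:meth:`Tensor.backward` on a scalar walks the graph in reverse
topological order and accumulates gradients on every node, which also
makes intermediate activations inspectable (needed for gradient-weighted
activation maps).

Only the operations the model architecture needs are implemented:
broadcast arithmetic, matmul, ReLU/LeakyReLU/sigmoid, exp/log, axis
reductions, concatenation, reshape and integer-array row gathering.
Everything is float64; there is no device or dtype abstraction.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "stack_rows", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        if type(data) is np.ndarray and data.dtype == np.float64:
            self.data = data
        else:
            self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if not requires_grad:
            for p in _parents:
                if p.requires_grad:
                    requires_grad = True
                    break
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    # -- graph mechanics -----------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g) if self.requires_grad else None
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data**2))

        out._backward = _bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bwd(g: np.ndarray) -> None:
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    self._accumulate(np.outer(g, b) if a.ndim == 2 else g * b)
                elif a.ndim == 1:
                    self._accumulate(b @ g)
                else:
                    self._accumulate(g @ b.T)
            if other.requires_grad:
                if a.ndim == 1:
                    other._accumulate(np.outer(a, g) if b.ndim == 2 else g * a)
                elif b.ndim == 1:
                    other._accumulate(a.T @ g)
                else:
                    other._accumulate(a.T @ g)

        out._backward = _bwd
        return out

    # -- nonlinearities ------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        mask = self.data > 0

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = _bwd
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))
        factor = np.where(self.data > 0, 1.0, slope)

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * factor)

        out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = _bwd
        return out

    # -- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g2, self.data.shape))

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int = 0) -> "Tensor":
        """Max-reduce one axis; subgradient routes to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            grad = np.zeros_like(self.data)
            grid = np.indices(out.data.shape)
            index = list(grid)
            index.insert(axis % self.data.ndim, idx)
            grad[tuple(index)] = g
            self._accumulate(grad)

        out._backward = _bwd
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = _bwd
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.T)

        out._backward = _bwd
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accumulate(grad)

        out._backward = _bwd
        return out

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Row lookup with an integer array; rows may repeat."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], _parents=(self,))

        def _bwd(g: np.ndarray) -> None:
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, index, g)
                self._accumulate(grad)

        out._backward = _bwd
        return out

    def softmax_rows(self, mask: np.ndarray | None = None) -> "Tensor":
        """Row-wise softmax of a 2-D tensor.

        `mask` is a boolean matrix; False entries get probability zero
        (their logits are pushed to -inf before normalization). Rows with
        an empty mask produce all-zero rows rather than NaN.
        """
        logits = self
        if mask is not None:
            penalty = np.where(mask, 0.0, -1e30)
            logits = logits + Tensor(penalty)
        shift = np.max(logits.data, axis=1, keepdims=True)
        shift = np.where(np.isfinite(shift), shift, 0.0)
        e = (logits - Tensor(shift)).exp()
        if mask is not None:
            e = e * Tensor(mask.astype(np.float64))
        denom = e.sum(axis=1, keepdims=True)
        safe = Tensor(np.where(denom.data == 0.0, 1.0, 0.0))
        return e / (denom + safe)


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bwd(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bwd
    return out


def stack_rows(tensors: Iterable[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D matrix (axis 0)."""
    return concatenate([t.reshape(1, -1) for t in tensors], axis=0)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    if p >= 1.0:
        return x * Tensor(np.zeros_like(x.data))
    keep = (rng.random(x.data.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)
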