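"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for recurrent sequence models: broadcast-aware
elementwise arithmetic, matmul, the sigmoid/tanh nonlinearities, slicing,
concatenation, log-sum-exp, and an embedding-row gather whose gradient
scatters with ``np.add.at``.  Gradients are accumulated on a tape and
released by topological traversal from the loss.

Correctness is established by finite-difference checks in the test suite,
not by construction; keep new ops covered there.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: backward closures may pass views of a child's grad
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
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
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other: float) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = Tensor(a.data @ b.data, parents=(a, b))

        def bw(g: np.ndarray) -> None:
            ad, bd = a.data, b.data
            if a.requires_grad:
                if ad.ndim == 1 and bd.ndim == 2:
                    a._accum(g @ bd.T)
                elif ad.ndim == 2 and bd.ndim == 2:
                    a._accum(g @ bd.T if g.ndim == 2 else np.outer(g, bd))
                else:
                    raise NotImplementedError
            if b.requires_grad:
                if ad.ndim == 1 and bd.ndim == 2:
                    b._accum(np.outer(ad, g))
                elif ad.ndim == 2 and bd.ndim == 2:
                    b._accum(ad.T @ g)
                else:
                    raise NotImplementedError

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    def sum(self, axis=None) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape).copy())
                else:
                    self._accum(
                        np.broadcast_to(
                            np.expand_dims(g, axis), self.data.shape
                        ).copy()
                    )

        out._backward = bw
        return out


def _as_tensor(x: "Tensor | float | np.ndarray") -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -50, 50)))
    out = Tensor(s, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bw(g: np.ndarray) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stabilized log(sum(exp(x))) along ``axis``."""
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    val = np.squeeze(m + np.log(s), axis=axis)
    softmax = e / s
    out = Tensor(val, parents=(x,))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(np.expand_dims(g, axis) * softmax)

    out._backward = bw
    return out


def rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of an embedding table; gradient scatters back."""
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(table.data[indices], parents=(table,))

    def bw(g: np.ndarray) -> None:
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.data)
            np.add.at(table.grad, indices, g)

    out._backward = bw
    return out


def dropout_mask(
    x: Tensor, p: float, rng: np.random.Generator, training: bool
) -> Tensor:
    """Inverted dropout: identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


def sgd_step(params: Sequence[Parameter], lr: float, clip_norm: float = 0.0) -> float:
    """One SGD update in place; returns the (pre-clip) global gradient norm."""
    sq = 0.0
    for p in params:
        if p.grad is not None:
            sq += float((p.grad * p.grad).sum())
    norm = float(np.sqrt(sq))
    scale = 1.0
    if clip_norm > 0.0 and norm > clip_norm:
        scale = clip_norm / norm
    for p in params:
        if p.grad is not None:
            p.data -= lr * scale * p.grad
            p.grad = None
    return norm


def zero_grads(params: Sequence[Parameter]) -> None:
    for p in params:
        p.grad = None
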