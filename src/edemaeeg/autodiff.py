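"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the sequence classifiers in :mod:`edemaeeg.models`:
broadcast-aware elementwise ops, (batched) matmul, reductions, shape ops and
the usual nonlinearities.  Gradients are accumulated by topological-order
backprop from a scalar loss.  Correctness is pinned by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = ["Tensor", "softplus_np", "no_grad"]

ArrayLike = Union["Tensor", np.ndarray, float, int]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference); ops return plain Tensors."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def softplus_np(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False,
                 _prev: Sequence["Tensor"] = ()) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev = tuple(_prev)

    # -- helpers ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _wrap(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def _child(self, data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        if not _grad_enabled:
            return Tensor(data)
        return Tensor(data, requires_grad=any(p.requires_grad for p in parents),
                      _prev=[p for p in parents if p.requires_grad])

    # -- elementwise -----------------------------------------------------
    def __add__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out = self._child(self.data + other.data, (self, other))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = self._wrap(other)
        out = self._child(self.data * other.data, (self, other))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._wrap(other) + (-self)

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        return self * self._wrap(other).pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = self._child(self.data ** p, (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))
        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        out = self._child(np.exp(self.data), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = self._child(np.log(self.data), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        out = self._child(np.tanh(self.data), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data ** 2))
        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = self._child(s, (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))
        out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        out = self._child(np.maximum(self.data, 0.0), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = _bw
        return out

    def softplus(self) -> "Tensor":
        out = self._child(softplus_np(self.data), (self,))

        def _bw() -> None:
            if self.requires_grad:
                s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
                self._accum(out.grad * s)
        out._backward = _bw
        return out

    # -- linear algebra / shape -----------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = self._child(np.matmul(self.data, other.data), (self, other))

        def _bw() -> None:
            g = out.grad
            if self.requires_grad:
                gb = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(gb, self.data.shape))
            if other.requires_grad:
                ga = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(ga, other.data.shape))
        out._backward = _bw
        return out

    __matmul__ = matmul

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = self._child(np.swapaxes(self.data, a, b), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))
        out._backward = _bw
        return out

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        out = self._child(self.data.reshape(*shape), (self,))

        def _bw() -> None:
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))
        out._backward = _bw
        return out

    def slice_last(self, start: int, stop: int) -> "Tensor":
        """Contiguous slice along the last axis."""
        out = self._child(self.data[..., start:stop], (self,))

        def _bw() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[..., start:stop] = out.grad
                self._accum(g)
        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw() -> None:
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - np.max(self.data, axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- backprop --------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort (graphs can exceed recursion limits)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward()
        # break closure<->node reference cycles so the graph frees promptly
        for t in topo:
            t._backward = None
            t._prev = ()
            if not t.requires_grad:
                t.grad = None
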