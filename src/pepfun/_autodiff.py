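"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
``backward()`` topologically sorts the tape and accumulates gradients. The
op set is exactly what the classifier and student networks need: broadcasted
arithmetic, batched matmul, activations, reductions, slicing/concatenation,
softmax, embedding lookup, and clipped/kinked elementwise min/max whose
subgradient convention at the kink is the constant branch (gradient flows
only where the variable branch is strictly active).

Everything is CPU numpy; determinism follows from seeding the numpy
generators that initialize parameters and order data.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()
        self.name = name
        self._grad_borrowed = False

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # Keep gradients in the parameter's own dtype (no silent float64
        # upcast). The first contribution is borrowed without copying —
        # reverse topological order guarantees a child's grad is final before
        # its backward runs — and the first reuse copies (copy-on-write).
        if self.grad is None:
            g = np.asarray(g)
            if g.dtype == self.data.dtype and g.shape == self.data.shape:
                self.grad = g
                self._grad_borrowed = True
            else:
                self.grad = np.broadcast_to(g, self.data.shape).astype(self.data.dtype)
                self._grad_borrowed = False
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _scalar(x):
        """Python scalar for weak dtype promotion, or None if not a scalar."""
        if isinstance(x, (int, float, np.integer, np.floating)):
            return float(x)
        return None

    def __add__(self, other):
        s = Tensor._scalar(other)
        if s is not None:
            def backward():
                if self.requires_grad:
                    self._accum(out.grad)

            out = Tensor._make(self.data + s, (self,), backward)
            return out
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        s = Tensor._scalar(other)
        if s is not None:
            return self + (-s)
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        s = Tensor._scalar(other)
        if s is not None:
            return (-self) + s
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        s = Tensor._scalar(other)
        if s is not None:
            def backward():
                if self.requires_grad:
                    self._accum(out.grad * s)

            out = Tensor._make(self.data * s, (self,), backward)
            return out
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        s = Tensor._scalar(other)
        if s is not None:
            return self * (1.0 / s)
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -out.grad * self.data / other.data ** 2, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = np.matmul(self.data, other.data)

        def backward():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data * (1 - out_data))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1 - out_data ** 2))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def exp(self):
        out_data = np.exp(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    # -- kinked elementwise ops (constant branch wins at the kink) ---------

    def minimum(self, const: float):
        """min(x, c); gradient flows only where x < c strictly."""
        mask = self.data < const
        out_data = np.where(mask, self.data, const)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def maximum(self, const: float):
        """max(x, c); gradient flows only where x > c strictly."""
        mask = self.data > const
        out_data = np.where(mask, self.data, const)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % self.data.ndim for a in axes):
                        g = np.expand_dims(g, ax)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient routes to the first arg-max (ties)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)

        def backward():
            if self.requires_grad:
                g = out.grad if keepdims else np.expand_dims(out.grad, axis)
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), g, axis)
                self._accum(full)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = Tensor._make(self.data.reshape(*shape), (self,), backward)
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        out = Tensor._make(self.data.transpose(*axes), (self,), backward)
        return out

    def __getitem__(self, key):
        out_data = self.data[key]
        parts = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(p, (slice, int)) for p in parts)

        def backward():
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # basic indexing never repeats an element
                    full[key] += out.grad
                else:
                    np.add.at(full, key, out.grad)
                self._accum(full)

        out = Tensor._make(out_data, (self,), backward)
        return out

    # -- fused ops ---------------------------------------------------------

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward():
            if self.requires_grad:
                g = out.grad
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        out = Tensor._make(out_data, (self,), backward)
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(out.grad, i, axis=axis))

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)
    out_data = weight.data[indices]

    def backward():
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, indices, out.grad)
            weight._accum(full)

    out = Tensor._make(out_data, (weight,), backward)
    return out


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager suspending tape recording (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False
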