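"""Tape-based reverse-mode autodiff on numpy arrays.

Only what the registration/annotation networks require: elementwise
arithmetic with broadcasting, reductions, slicing, concatenation, and the
exponential family.  Layer-level operations with custom backward passes
(convolutions, pooling, resizing, warping) live in
:mod:`wormalign.nn.functional`.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape of a broadcast operand."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = _parents
        self._backward = None

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, grad: np.ndarray) -> None:
        # grads are never mutated in place, so storing a reference is safe
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
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
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the closure cycles (node._backward captures node) so the
        # graph frees by reference counting instead of waiting for gc, and
        # drop intermediate gradients; leaf tensors (parameters) keep theirs
        for node in topo:
            is_leaf = not node._parents
            node._backward = None
            node._parents = ()
            if node is not self and not is_leaf:
                node.grad = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            # scalar fast path; also avoids promoting float32 data
            out = Tensor(self.data + other, self.requires_grad, (self,))
            out._backward = lambda: self.accumulate(out.grad)
            return out
        other = Tensor.as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            self.accumulate(_unbroadcast(out.grad, self.shape))
            other.accumulate(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(-out.grad)
        return out

    def __sub__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self + (-other)
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            out = Tensor(self.data * other, self.requires_grad, (self,))
            out._backward = lambda: self.accumulate(out.grad * other)
            return out
        other = Tensor.as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            self.accumulate(_unbroadcast(out.grad * other.data, self.shape))
            other.accumulate(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self * (1.0 / other)
        other = Tensor.as_tensor(other)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def backward():
            self.accumulate(_unbroadcast(out.grad / other.data, self.shape))
            other.accumulate(
                _unbroadcast(-out.grad * self.data / other.data**2, other.shape)
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(
            out.grad * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad * 0.5 / out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad * np.sign(self.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad * (self.data > 0))
        return out

    def clip_min(self, floor: float):
        """max(x, floor); gradient passes where x > floor."""
        out = Tensor(np.maximum(self.data, floor), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad * (self.data > floor))
        return out

    # -- reductions / shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad.reshape(self.shape))
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda: self.accumulate(out.grad.transpose(np.argsort(axes)))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def backward():
            g = np.zeros_like(self.data)
            g[key] = out.grad
            self.accumulate(g)

        out._backward = backward
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )

    def backward():
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            t.accumulate(out.grad[tuple(sl)])

    out._backward = backward
    return out


def add_n(tensors: list[Tensor]) -> Tensor:
    """Sum a list of same-shape tensors."""
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out
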