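"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the denoiser network and losses need:
broadcasting arithmetic, matmul, reductions, indexing/embedding lookup,
concatenation, elementwise nonlinearities, the 3-vector cross product and a
numerically stable log-softmax.  Everything is float64.  The graph is built
eagerly; ``Tensor.backward()`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "cross", "log_softmax", "as_tensor",
           "index_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [self]
        # iterative post-order topological sort
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents
                         if p.requires_grad and id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        assert np.isscalar(p)
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))
        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        return self._make(self.data @ other.data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a, b):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, key, g)
                self._accum(acc)
        return self._make(self.data[key], (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)
        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))
        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))
        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            if self.requires_grad:
                self._accum(g * (sig + self.data * sig * (1.0 - sig)))
        return self._make(self.data * sig, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    ax = axis % tensors[0].ndim
    sizes = [t.shape[ax] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def backward(g):
        pieces = np.split(g, splits, axis=ax)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(p)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=ax))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Cross product along the last axis (length 3).

    d<g, a x b> gives grad_a = b x g and grad_b = g x a.
    """
    a, b = as_tensor(a), as_tensor(b)
    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.cross(b.data, g), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.cross(g, a.data), b.shape))
    out = Tensor(np.cross(a.data, b.data))
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = backward
    return out


def index_sum(x: Tensor, index: np.ndarray, num_segments: int) -> Tensor:
    """Scatter-add rows of ``x`` into ``num_segments`` bins along axis 0
    (segment sum); the adjoint of row gathering."""
    x = as_tensor(x)
    out_data = np.zeros((num_segments,) + x.shape[1:])
    np.add.at(out_data, index, x.data)
    def backward(g):
        if x.requires_grad:
            x._accum(g[index])
    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (fused forward/backward)."""
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    softmax = np.exp(out_data)
    def backward(g):
        if x.requires_grad:
            x._accum(g - softmax * g.sum(axis=axis, keepdims=True))
    out = Tensor(out_data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out
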