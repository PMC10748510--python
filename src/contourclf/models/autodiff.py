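"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Just enough machinery for the recurrent and attention models in this
package: broadcasting elementwise arithmetic, matmul, the usual
nonlinearities, reductions, indexing/concatenation and an embedding
gather.  Gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "sigmoid", "tanh", "relu", "softmax",
           "binary_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward, req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(self.data / other.data, (self, other), backward, req)

    def __matmul__(self, other):
        other = self._coerce(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward, req)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
        return Tensor._make(self.data[idx], (self,), backward, self.requires_grad)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))
        return Tensor._make(self.data.reshape(*shape), (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))
        return Tensor._make(self.data.transpose(axes), (self,), backward, self.requires_grad)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)
        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        start = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, start + size)
                t._accumulate(g[tuple(sl)])
            start += size

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward, req)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.squeeze(part, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward, req)


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -500, 500)
    out_data = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                        np.exp(z) / (1.0 + np.exp(z)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))
    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data ** 2))
    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)
    return Tensor._make(x.data * mask, (x,), backward, x.requires_grad)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - dot))
    return Tensor._make(out_data, (x,), backward, x.requires_grad)


def binary_cross_entropy(p: Tensor, target: np.ndarray, eps: float = 1e-9) -> Tensor:
    """Mean BCE of predicted probabilities ``p`` against binary targets."""
    target = np.asarray(target, dtype=np.float64)
    p_c = Tensor._make(np.clip(p.data, eps, 1.0 - eps), (p,),
                       lambda g: p._accumulate(
                           g * ((p.data > eps) & (p.data < 1.0 - eps))),
                       p.requires_grad)
    loss = -(Tensor(target) * p_c.log() + Tensor(1.0 - target) * (1.0 - p_c).log())
    return loss.mean()
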