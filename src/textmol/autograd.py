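"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for small transformer models: broadcasting elementwise
arithmetic, batched matmul, reshape/transpose, reductions, exp/log/relu,
embedding lookup, and composed softmax / layer-norm / cross-entropy helpers.
Float64 throughout; clarity over speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "softmax", "layer_norm", "cross_entropy",
           "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
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
                if id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- primitive operations ---------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(np.add(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (as_tensor(other) * -1.0)

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (self * -1.0)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(np.multiply(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float) -> "Tensor":
        out = _make(np.power(self.data, exponent), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    g * exponent * np.power(self.data, exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = _make(np.matmul(self.data, other.data), (self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        value = np.exp(self.data)
        out = _make(value, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * value)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = _make(np.log(self.data), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = _make(self.data * mask, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        value = np.tanh(self.data)
        out = _make(value, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - value * value))

        out._backward = backward
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if not self.requires_grad:
                return
            grad = g
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        out = _make(self.data.reshape(*shape), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        out = _make(self.data.transpose(*axes), (self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inverse))

        out._backward = backward
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = _make(np.swapaxes(self.data, a, b), (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        out._backward = backward
        return out


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    indices = np.asarray(indices)
    out = _make(weight.data[indices], (weight,))

    def backward(g):
        if weight.requires_grad:
            if weight.grad is None:
                weight.grad = np.zeros_like(weight.data)
            np.add.at(weight.grad, indices, g)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5) * gain + bias


def cross_entropy(logits: Tensor, targets: np.ndarray,
                  mask: np.ndarray) -> Tensor:
    """Mean cross-entropy over positions where ``mask`` is 1.

    ``logits`` has shape (..., V); ``targets`` and ``mask`` share the leading
    shape.  Implemented with a one-hot contraction so vocabulary sizes stay
    small and explicit.
    """
    vocab = logits.shape[-1]
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    log_z = shifted.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shifted - log_z
    one_hot = np.eye(vocab)[np.asarray(targets)]
    picked = (log_probs * one_hot).sum(axis=-1)
    mask = np.asarray(mask, dtype=np.float64)
    total = float(mask.sum())
    if total <= 0:
        raise ValueError("cross_entropy mask selects no positions")
    return (picked * mask).sum() * (-1.0 / total)
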