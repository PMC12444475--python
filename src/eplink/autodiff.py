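"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's classifier is small (tens of thousands of parameters, batch
sizes in the tens), so a compact tape-based engine is sufficient: every
operation builds a node holding its inputs and a closure that accumulates
gradients into them.  Only the primitives the Transformer generator and the
MLP discriminator need are provided.

All arrays are float64.  Constants (inputs, dropout masks, labels) are
wrapped in :class:`Tensor` like parameters; gradients are simply ignored for
tensors the optimiser does not track.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "backward", "Adam", "zero_grads"]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self.grad += _unbroadcast(g, self.data.shape)
            other.grad += _unbroadcast(g, other.data.shape)

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def bw(g):
            self.grad += -g

        out._bw = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self.grad += _unbroadcast(g * other.data, self.data.shape)
            other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            self.grad += _unbroadcast(g / other.data, self.data.shape)
            other.grad += _unbroadcast(
                -g * self.data / (other.data**2), other.data.shape
            )

        out._bw = bw
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self.grad += _unbroadcast(ga, self.data.shape)
            other.grad += _unbroadcast(gb, other.data.shape)

        out._bw = bw
        return out

    def pow_const(self, c: float):
        out = Tensor(self.data**c, (self,))

        def bw(g):
            self.grad += g * c * self.data ** (c - 1)

        out._bw = bw
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.grad += np.broadcast_to(g, self.data.shape)

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))

        def bw(g):
            self.grad += g * out.data

        out._bw = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def bw(g):
            self.grad += g / self.data

        out._bw = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bw(g):
            self.grad += g * (self.data > 0)

        out._bw = bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), (self,))

        def bw(g):
            self.grad += g * np.where(self.data > 0, 1.0, slope)

        out._bw = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, (self,))

        def bw(g):
            self.grad += g * s * (1.0 - s)

        out._bw = bw
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), (self,))

        def bw(g):
            self.grad += g.reshape(self.data.shape)

        out._bw = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), (self,))
        inv = np.argsort(axes)

        def bw(g):
            self.grad += g.transpose(inv)

        out._bw = bw
        return out

    def softmax(self):
        """Softmax over the last axis (shift by a detached max for stability)."""
        m = self.data.max(axis=-1, keepdims=True)
        e = (self - m).exp()
        return e / e.sum(axis=-1, keepdims=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.grad += piece

    out._bw = bw
    return out


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum a gradient over the axes numpy broadcast during the forward pass."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


def backward(loss: Tensor) -> None:
    """Populate ``.grad`` on every tensor reachable from ``loss``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    for t in topo:
        t.grad = np.zeros_like(t.data)
    loss.grad = np.ones_like(loss.data)
    for t in reversed(topo):
        if t._bw is not None:
            t._bw(t.grad)


def zero_grads(params: dict[str, Tensor]) -> None:
    for p in params.values():
        p.grad = None


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
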