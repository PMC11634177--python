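"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in :mod:`actin.model` is small (tens of parameter tensors, graphs
with a few dozen atoms, 2-token attention) and is trained on CPU, so a compact
tape-based engine over dense numpy arrays is sufficient.  Only the primitives
the network needs are implemented; each primitive's gradient is exercised by a
numerical check in the test suite.

Conventions
-----------
* ``Tensor`` wraps a float64 ``ndarray``.  Plain ndarrays / scalars appearing
  in arithmetic are treated as constants (no gradient).
* Broadcasting follows numpy; gradients are summed back to the parent shape.
* Node-selection style operations (top-k indices, argmax) are computed outside
  the tape on ``.data`` and enter the graph only through gather operations,
  which is the standard straight-through treatment for discrete pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "softmax", "layer_norm"]


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._prev: tuple = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep (N blocks x layers)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        if not self.requires_grad:
            return
        grad = _sum_to_shape(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
                return
            ga = np.matmul(g, np.swapaxes(b, -1, -2)) if b.ndim > 1 else np.multiply.outer(g, b)
            gb = np.matmul(np.swapaxes(a, -1, -2), g) if a.ndim > 1 else np.multiply.outer(a, g)
            self._accum(_sum_to_shape(ga, a.shape))
            other._accum(_sum_to_shape(gb, b.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def reciprocal(self):
        out_data = 1.0 / self.data

        def bw(g):
            self._accum(-g * out_data * out_data)

        return Tensor._make(out_data, (self,), bw)

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accum(g * factor)

        return Tensor._make(self.data * factor, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(out_data, (self,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = out_data if keepdims else np.expand_dims(out_data, axis)
        # route gradient to the first maximal entry only (consistent tie-break)
        is_max = self.data == expanded
        first = np.cumsum(is_max, axis=axis) == 1
        mask = is_max & first

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape) * mask)

        return Tensor._make(out_data, (self,), bw)

    def take0(self, indices: np.ndarray):
        """Gather rows along axis 0 (repeats allowed)."""
        indices = np.asarray(indices)
        out_data = self.data[indices]

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, indices, g)
            self._accum(acc)

        return Tensor._make(out_data, (self,), bw)

    def gather_nodes(self, idx: np.ndarray):
        """For a (B, n, d) tensor gather axis-1 rows per batch: out[b, i] = x[b, idx[b, i]]."""
        idx = np.asarray(idx)
        b_ix = np.arange(self.data.shape[0])[:, None]
        out_data = self.data[b_ix, idx]

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, (b_ix, idx), g)
            self._accum(acc)

        return Tensor._make(out_data, (self,), bw)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(out_data, tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return Tensor._make(out_data, (x,), bw)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance (no affine part)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out_data = xc * inv

    def bw(g):
        d = x.data.shape[-1]
        g_mean = g.mean(axis=-1, keepdims=True)
        gy_mean = (g * out_data).mean(axis=-1, keepdims=True)
        x._accum(inv * (g - g_mean - out_data * gy_mean))

    return Tensor._make(out_data, (x,), bw)
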