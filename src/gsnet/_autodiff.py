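"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the message-passing networks
need: dense algebra, elementwise maps, row gather/scatter and
segment reductions (the graph analogue of batched attention), all with
analytically derived adjoints. Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims numpy added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff core --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free interior tapes eagerly
            if node is not self:
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = any(p.requires_grad for p in parents)
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._make(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) - self

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise maps -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def ssp(self):
        """Shifted softplus ln(1+e^x) - ln 2; stable for large |x|."""
        out_data = np.logaddexp(0.0, self.data) - np.log(2.0)

        def bw(g):
            # d/dx softplus = logistic sigmoid
            self._accum(g * _sigmoid(self.data))

        return Tensor._make(out_data.astype(self.dtype), (self,), bw)

    # -- reductions & reshaping -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bw(g):
            self._accum(g.reshape(self.data.shape))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]`` along axis 0 (differentiable scatter-add adjoint)."""
    index = np.asarray(index, dtype=np.intp)

    def bw(g):
        out = np.zeros_like(t.data)
        np.add.at(out, index, g)
        t._accum(out)

    return Tensor._make(t.data[index], (t,), bw)


def segment_sum(t: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``n_segments`` buckets given per-row segment ids."""
    segments = np.asarray(segments, dtype=np.intp)
    out_data = np.zeros((n_segments,) + t.data.shape[1:], dtype=t.data.dtype)
    np.add.at(out_data, segments, t.data)

    def bw(g):
        t._accum(g[segments])

    return Tensor._make(out_data, (t,), bw)


def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of ``logits`` normalized within each segment (along axis 0).

    The per-segment max shift is treated as a constant; softmax is invariant
    to it, so the gradient is exact.
    """
    segments = np.asarray(segments, dtype=np.intp)
    m = np.full((n_segments,) + logits.data.shape[1:], -np.inf, dtype=logits.data.dtype)
    np.maximum.at(m, segments, logits.data)
    shifted = logits - Tensor(m[segments])
    z = shifted.exp()
    denom = segment_sum(z, segments, n_segments)
    return z / gather_rows(denom, segments)
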