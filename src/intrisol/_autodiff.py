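"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations the graph
transformer needs: broadcasting arithmetic, matmul (including stacked
head-wise matmul), exp/log/relu/softmax, reductions, reshapes, row gather and
segment-sum scatter.  Gradient correctness is asserted against central finite
differences in the test suite.

Not a general framework: no higher-order gradients, no in-place ops, float64
throughout (CPU determinism over speed).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))
        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))
        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))
        return Tensor._from_op(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))
        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y)
        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._from_op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)
        return Tensor._from_op(self.data * mask, (self,), backward)

    def softplus(self):
        # stable log(1 + exp(x))
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g, a=self, s=sig):
            if a.requires_grad:
                a._accum(g * s)
        return Tensor._from_op(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        def backward(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))
        return Tensor._from_op(y, (self,), backward)

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.full(a.shape, g))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy())
        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accum(g.reshape(old))
        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accum(g.transpose(inv))
        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    # -- autodiff machinery ---------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros(self.shape)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        self._accum(np.asarray(grad, float))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)
    def backward(g, ts=tensors, offs=offs, axis=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row selection x[idx] along axis 0; backward scatter-adds."""
    idx = np.asarray(idx, int)
    def backward(g, a=x, idx=idx):
        if a.requires_grad:
            out = np.zeros(a.shape)
            np.add.at(out, idx, g)
            a._accum(out)
    return Tensor._from_op(x.data[idx], (x,), backward)


def segment_sum(x: Tensor, idx: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row indices."""
    idx = np.asarray(idx, int)
    out_data = np.zeros((n_segments,) + x.shape[1:])
    np.add.at(out_data, idx, x.data)
    def backward(g, a=x, idx=idx):
        if a.requires_grad:
            a._accum(g[idx])
    return Tensor._from_op(out_data, (x,), backward)
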