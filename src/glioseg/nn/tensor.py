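"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float64 ndarray and
records, for each operation, a closure that propagates the upstream gradient
to its parents.  ``Tensor.backward()`` runs the closures in reverse
topological order.  Only the operations needed by the models in this package
are provided (elementwise arithmetic, matmul, reductions, shape ops, 2-D
convolution via im2col, nearest-neighbour upsampling, concatenation).

All computation is float64 and purely numpy, so results are bit-reproducible
for a fixed seed regardless of call order.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "upsample_nearest2x", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data, dtype=np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- op construction --------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- elementwise arithmetic -------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g, a.shape))
            b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g * b.data, a.shape))
            b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            a._accumulate(_unbroadcast(g / b.data, a.shape))
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        a = self

        def backward(g):
            a._accumulate(g * p * np.power(a.data, p - 1))

        return Tensor._make(np.power(a.data, p), (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        # numerically stable logistic
        out_data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                            np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only in the open interval."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                grad = np.broadcast_to(g, a.shape)
            a._accumulate(grad.astype(np.float64, copy=True))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def backward(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(*axes)

    # -- matmul -------------------------------------------------------------

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                bt = np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(np.matmul(g, bt), a.shape))
            if b.requires_grad:
                at = np.swapaxes(a.data, -1, -2)
                b._accumulate(_unbroadcast(np.matmul(at, g), b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, backward)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    cols = np.ascontiguousarray(view.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * oh * ow, c * kh * kw
    )
    return cols, oh, ow


def _col2im(cols: np.ndarray, xshape, kh, kw, stride, pad):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    dx = np.zeros((n, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW input, OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wid = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = w.data.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        if w.requires_grad:
            w._accumulate((gm.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = gm @ wmat
            x._accumulate(_col2im(dcols, x.shape, kh, kw, stride, padding))

    return Tensor._make(out, parents, backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)
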