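"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each operation records its parents
together with closures that map the output gradient to parent-gradient
contributions.  ``Tensor.backward`` runs a topological sweep and accumulates
gradients into ``Tensor.grad``.  Only the operations needed by the dual-view
context-recognition network are provided (dense/conv layers, LeakyReLU,
sigmoid/softplus, softmax attention, reductions, slicing, concatenation).

All forward values are plain ``numpy`` arrays; dtype follows the inputs, so
float64 can be used for gradient checking and float32 for training speed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


def _as_array(x) -> Array:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable[[Array], Array]]] = ()):
        self.data = np.asarray(data)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib
        # interior nodes that were explicitly marked keep their gradient too
        # (leaves were handled above)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def constant(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


# -- primitive operations --------------------------------------------------

def add(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = a.data + b.data
    return Tensor(out, parents=[
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ])


def mul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = a.data * b.data
    return Tensor(out, parents=[
        (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
        (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
    ])


def power(a, p: float) -> Tensor:
    a = constant(a)
    out = a.data ** p
    return Tensor(out, parents=[(a, lambda g: g * p * a.data ** (p - 1.0))])


def sqrt(a, eps: float = 0.0) -> Tensor:
    """Elementwise square root; ``eps`` bounds the derivative near zero."""
    a = constant(a)
    root = np.sqrt(a.data + eps)
    return Tensor(root, parents=[(a, lambda g: g * (0.5 / np.maximum(root, 1e-30)))])


def exp(a) -> Tensor:
    a = constant(a)
    out = np.exp(a.data)
    return Tensor(out, parents=[(a, lambda g: g * out)])


def log(a, eps: float = 0.0) -> Tensor:
    a = constant(a)
    return Tensor(np.log(a.data + eps), parents=[(a, lambda g: g / (a.data + eps))])


def matmul(a, b) -> Tensor:
    a, b = constant(a), constant(b)
    out = a.data @ b.data

    def ga(g: Array) -> Array:
        bd = b.data
        if bd.ndim == 1:
            return _unbroadcast(np.expand_dims(g, -1) * bd, a.data.shape)
        return _unbroadcast(g @ np.swapaxes(bd, -1, -2), a.data.shape)

    def gb(g: Array) -> Array:
        ad = a.data
        if ad.ndim == 1:
            return _unbroadcast(np.expand_dims(ad, -1) * np.expand_dims(g, -2), b.data.shape)
        return _unbroadcast(np.swapaxes(ad, -1, -2) @ g, b.data.shape)

    return Tensor(out, parents=[(a, ga), (b, gb)])


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = constant(a)
    mask = a.data > 0
    out = np.where(mask, a.data, slope * a.data)
    return Tensor(out, parents=[(a, lambda g: g * np.where(mask, 1.0, slope))])


def relu(a) -> Tensor:
    return leaky_relu(a, slope=0.0)


def sigmoid(a) -> Tensor:
    a = constant(a)
    x = a.data
    e = np.exp(-np.abs(x))  # stable: never overflows
    out = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    return Tensor(out, parents=[(a, lambda g: g * out * (1.0 - out))])


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; d/dx = sigmoid(x)."""
    a = constant(a)
    x = a.data
    out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    sig = 1.0 / (1.0 + np.exp(-x))
    return Tensor(out, parents=[(a, lambda g: g * sig)])


def softmax(a, axis: int = -1) -> Tensor:
    a = constant(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def grad(g: Array) -> Array:
        dot = (g * out).sum(axis=axis, keepdims=True)
        return out * (g - dot)

    return Tensor(out, parents=[(a, grad)])


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = constant(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def grad(g: Array) -> Array:
        if axis is None:
            return np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False)

    return Tensor(out, parents=[(a, grad)])


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = constant(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = constant(a)
    return Tensor(a.data.reshape(shape), parents=[(a, lambda g: g.reshape(a.data.shape))])


def transpose(a, axes=None) -> Tensor:
    a = constant(a)
    out = a.data.transpose(axes)
    if axes is None:
        inv = None
    else:
        inv = tuple(np.argsort(axes))
    return Tensor(out, parents=[(a, lambda g: g.transpose(inv))])


def take(a, idx) -> Tensor:
    a = constant(a)
    out = a.data[idx]

    def grad(g: Array) -> Array:
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        return buf

    return Tensor(out, parents=[(a, grad)])


def concat(parts: Iterable[Tensor], axis: int = 0) -> Tensor:
    parts = [constant(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def make_grad(i: int):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=[(p, make_grad(i)) for i, p in enumerate(parts)])


def conv1d(x, w, b=None, stride: int = 1) -> Tensor:
    """1-D cross-correlation in time-major layout.

    x: [B, T, C] (time-major, C contiguous), w: [K, C, O], bias: [O];
    returns [B, t_out, O].  With this layout the im2col window view is
    contiguous over (K, C), so the gather is a plain block copy and the
    whole operation is one BLAS matmul with no transposes.
    """
    x, w = constant(x), constant(w)
    xb, wb = x.data, w.data
    B, T, C = xb.shape
    K, Cw, O = wb.shape
    if C != Cw:
        raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
    if T < K:
        raise ValueError(f"conv1d input length {T} shorter than kernel {K}")
    t_out = (T - K) // stride + 1
    xb = np.ascontiguousarray(xb)
    sB, sT, sC = xb.strides
    cols = np.lib.stride_tricks.as_strided(
        xb, shape=(B, t_out, K, C), strides=(sB, sT * stride, sT, sC))
    cols2 = np.ascontiguousarray(cols).reshape(B, t_out, K * C)
    wmat = wb.reshape(K * C, O)
    out = cols2 @ wmat
    if b is not None:
        b = constant(b)
        out = out + b.data

    def gx(g: Array) -> Array:
        gcols = (g @ wmat.T).reshape(B, t_out, K, C)
        buf = np.zeros_like(xb)
        for k in range(K):
            buf[:, k:k + stride * t_out:stride, :] += gcols[:, :, k, :]
        return buf

    def gw(g: Array) -> Array:
        return (cols2.reshape(-1, K * C).T @ g.reshape(-1, O)).reshape(K, C, O)

    parents = [(x, gx), (w, gw)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 1))))
    return Tensor(out, parents=parents)


def weighted_sum(a, weights: Array) -> Tensor:
    """sum(weights * a) for a constant coefficient array ``weights``."""
    a = constant(a)
    w = np.asarray(weights)
    return Tensor(np.asarray((w * a.data).sum()), parents=[(a, lambda g: g * w)])


def pairwise_sq_dists(a, b) -> Tensor:
    """Squared Euclidean distance matrix between rows of a [N,D] and b [M,D]."""
    a, b = constant(a), constant(b)
    an = sum_(mul(a, a), axis=1, keepdims=True)          # [N,1]
    bn = reshape(sum_(mul(b, b), axis=1), (1, -1))       # [1,M]
    cross = matmul(a, transpose(b))                      # [N,M]
    d2 = add(add(an, bn), mul(cross, -2.0))
    # numerical guard: clamp tiny negatives from cancellation
    return relu(d2)


def pairwise_dists(a, b, eps: float = 1e-12) -> Tensor:
    return sqrt(pairwise_sq_dists(a, b), eps=eps)
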