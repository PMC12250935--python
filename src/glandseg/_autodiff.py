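"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small enough that a
straightforward define-by-run tape over float32 numpy arrays is adequate:
every primitive stores a closure that scatters the upstream gradient into
its parents, and :meth:`Tensor.backward` walks the tape in reverse
topological order.  Only the primitives the network actually needs are
implemented (elementwise arithmetic, matmul, gather, conv2d, layer norm,
reductions, reshapes); everything else — attention, bilinear sampling,
bicubic resizing — is composed from them and differentiated automatically.

All data is float32.  Gradients are accumulated into ``Tensor.grad`` as
plain numpy arrays; non-leaf gradients are kept only during the backward
pass.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "gelu",
    "layer_norm",
    "log",
    "exp",
    "sigmoid",
    "softmax",
    "take_rows",
    "clip",
    "relu",
    "tanh",
]


def _f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A node in the autodiff tape wrapping a float32 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- bookkeeping --------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if not g.flags.owndata else g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _f32(np.ones_like(self.data) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self and node._parents:
                    node.grad = None  # free non-leaf memory

    # -- operators ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), pow_(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p: float):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents if req else (),
                  backward=backward if req else None)


# -- arithmetic -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** np.float32(p)

    def bwd(g):
        a._accum(g * np.float32(p) * a.data ** np.float32(p - 1.0))

    return _make(out_data, (a,), bwd)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g, out_data=out_data):
        a._accum(g * out_data)

    return _make(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def bwd(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    from scipy.special import expit
    a = as_tensor(a)
    out_data = expit(a.data)

    def bwd(g, s=out_data):
        a._accum(g * s * (1.0 - s))

    return _make(out_data, (a,), bwd)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def bwd(g, t=out_data):
        a._accum(g * (1.0 - t * t))

    return _make(out_data, (a,), bwd)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        a._accum(g * (a.data > 0))

    return _make(out_data, (a,), bwd)


_GELU_C = np.float32(np.sqrt(2.0 / np.pi))


def gelu(a) -> Tensor:
    """GELU, tanh approximation (differentiated analytically)."""
    a = as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + np.float32(0.044715) * x ** 3)
    t = np.tanh(inner)
    out_data = 0.5 * x * (1.0 + t)

    def bwd(g, t=t):
        x_ = a.data
        dinner = _GELU_C * (1.0 + 3.0 * np.float32(0.044715) * x_ ** 2)
        da = 0.5 * (1.0 + t) + 0.5 * x_ * (1.0 - t * t) * dinner
        a._accum(g * da)

    return _make(out_data, (a,), bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is zero outside [lo, hi] (subgradient convention)."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)

    def bwd(g):
        mask = (a.data >= lo) & (a.data <= hi)
        a._accum(g * mask)

    return _make(out_data, (a,), bwd)


# -- shape ops --------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape) if isinstance(shape, (tuple, list)) else (shape,)
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), bwd)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g):
        a._accum(g.transpose(inv))

    return _make(out_data, (a,), bwd)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, slice, type(None), type(Ellipsis)))
               for i in items)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]
    basic = _is_basic_index(idx)

    def bwd(g):
        ga = np.zeros_like(a.data)
        if basic:  # basic indexing never aliases, so += suffices
            ga[idx] += g
        else:
            np.add.at(ga, idx, g)
        a._accum(ga)

    return _make(out_data, (a,), bwd)


def concat(parts: Sequence[Tensor], axis: int = 0) -> Tensor:
    parts = [as_tensor(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accum(g[tuple(sl)])

    return _make(out_data, tuple(parts), bwd)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            ga = np.broadcast_to(g, a.data.shape)
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            ga = np.broadcast_to(gg, a.data.shape)
        a._accum(_f32(ga))

    return _make(out_data, (a,), bwd)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, tuple):
        n = int(np.prod([a.data.shape[i] for i in axis]))
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis, keepdims), 1.0 / n)


def take_rows(a, rows: np.ndarray) -> Tensor:
    """Gather rows along axis 0: out[i...] = a[rows[i...]].

    ``rows`` is a constant integer array of any shape; the output has
    shape ``rows.shape + a.shape[1:]``.  Backward scatter-adds.
    """
    a = as_tensor(a)
    rows = np.asarray(rows)
    out_data = a.data[rows]

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, rows, g)
        a._accum(ga)

    return _make(out_data, (a,), bwd)


# -- fused numerical primitives --------------------------------------

def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax; tolerates -inf logits (masked entries).

    Rows must contain at least one finite entry — callers enforce the
    all-masked fallback before reaching here.
    """
    a = as_tensor(a)
    m = np.max(a.data, axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = e / s

    def bwd(g, out_data=out_data):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), bwd)


def layer_norm(a, weight, bias, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    a, weight, bias = as_tensor(a), as_tensor(weight), as_tensor(bias)
    x = a.data
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.float32(eps))
    xhat = xc * inv
    out_data = xhat * weight.data + bias.data

    def bwd(g, xhat=xhat, inv=inv):
        if weight.requires_grad:
            red = tuple(range(g.ndim - 1))
            weight._accum((g * xhat).sum(axis=red))
        if bias.requires_grad:
            red = tuple(range(g.ndim - 1))
            bias._accum(g.sum(axis=red))
        if a.requires_grad:
            dxhat = g * weight.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            a._accum(inv * (dxhat - m1 - xhat * m2))

    return _make(out_data, (a, weight, bias), bwd)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), channels-first, zero padding.

    x: (Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    cin, H, W = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"conv2d channel mismatch: {cin} vs {cin2}")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (Cin, Ho, Wo, kh, kw)
    out_data = np.einsum("oikl,ihwkl->ohw", w.data, win, optimize=True)
    if b is not None:
        out_data = out_data + b.data[:, None, None]
    Ho, Wo = out_data.shape[1:]

    def bwd(g, win=win):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if w.requires_grad:
            w._accum(np.einsum("ohw,ihwkl->oikl", g, win, optimize=True))
        if x.requires_grad:
            dcols = np.einsum("ohw,oikl->ihwkl", g, w.data, optimize=True)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, ki:ki + Ho * stride:stride, kj:kj + Wo * stride:stride] += dcols[:, :, :, ki, kj]
            if padding:
                dxp = dxp[:, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, bwd)


def numeric_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                     eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar function — test oracle."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp.astype(np.float32)) - f(xm.astype(np.float32))) / (2 * eps)
        it.iternext()
    return g
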