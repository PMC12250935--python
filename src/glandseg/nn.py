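"""Layers, parameter containers, optimizer and resampling helpers.

Everything here is generic plumbing shared by the encoder, pixel decoder
and transformer decoder: Linear / LayerNorm / MLP / Conv2d modules with
seeded truncated-normal initialization, an AdamW optimizer with parameter
groups, sinusoidal 2-D positional encodings, and separable interpolation
matrices (bilinear and Keys bicubic) used for all fixed-factor resizing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ._autodiff import Tensor, conv2d, gelu, layer_norm, matmul

__all__ = [
    "Module", "Parameter", "Linear", "LayerNorm", "Mlp", "Conv2d",
    "AdamW", "trunc_normal", "sinusoidal_position_encoding",
    "resize_matrix", "resize_map", "resize_map_np",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to ±2 std (values re-drawn by clipping)."""
    x = rng.standard_normal(shape)
    np.clip(x, -2.0, 2.0, out=x)
    return (x * std).astype(np.float32)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with recursive discovery, torch-like but tiny."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        seen: set[int] = set()
        self._collect(out, seen)
        return out

    def _collect(self, out, seen):
        for v in self.__dict__.values():
            self._collect_value(v, out, seen)

    @staticmethod
    def _collect_value(v, out, seen):
        if isinstance(v, Parameter):
            if id(v) not in seen:
                seen.add(id(v))
                out.append(v)
        elif isinstance(v, Module):
            v._collect(out, seen)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect_value(item, out, seen)

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._state("", out)
        return out

    def _state(self, prefix: str, out):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out[name] = v.data
            elif isinstance(v, Module):
                v._state(name + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._state(f"{name}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = item.data

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]} ...")
        self._load("", state)

    def _load(self, prefix: str, state):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                if v.data.shape != state[name].shape:
                    raise ValueError(f"shape mismatch for {name}: "
                                     f"{v.data.shape} vs {state[name].shape}")
                v.data = state[name].astype(np.float32).copy()
            elif isinstance(v, Module):
                v._load(name + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._load(f"{name}.{i}.", state)
                    elif isinstance(item, Parameter):
                        item.data = state[f"{name}.{i}"].astype(np.float32).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, std: float = 0.02):
        self.weight = Parameter(trunc_normal(rng, (n_in, n_out), std))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class Mlp(Module):
    """Two-layer feed-forward expansion with GELU."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 n_out: int | None = None):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, n_out if n_out is not None else dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class Conv2d(Module):
    def __init__(self, n_in: int, n_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int = 0, bias: bool = True, std: float = 0.02):
        self.weight = Parameter(trunc_normal(rng, (n_out, n_in, kernel, kernel), std))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class AdamW:
    """AdamW with optional per-group learning-rate multipliers.

    ``groups`` is a list of (params, lr_scale) pairs; the backbone group
    typically uses scale 0.1.  For speed all parameters are flattened
    into one contiguous buffer at construction (each ``Parameter.data``
    becomes a view into it), so one step is a handful of vectorized
    numpy operations regardless of the number of parameter arrays.
    """

    def __init__(self, groups, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05,
                 clip_grad_norm: float | None = 1.0):
        if groups and not isinstance(groups[0], tuple):
            groups = [(groups, 1.0)]
        self.groups = [(list(ps), float(s)) for ps, s in groups]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_grad_norm = clip_grad_norm
        self.t = 0
        # flatten: params become views into one buffer
        self._params: list[Parameter] = [p for ps, _ in self.groups for p in ps]
        total = sum(p.data.size for p in self._params)
        self._flat = np.empty(total, dtype=np.float32)
        self._lr_scale = np.empty(total, dtype=np.float32)
        self._slices: list[slice] = []
        off = 0
        for ps, scale in self.groups:
            for p in ps:
                n = p.data.size
                sl = slice(off, off + n)
                self._flat[sl] = p.data.ravel()
                self._lr_scale[sl] = scale
                p.data = self._flat[sl].reshape(p.data.shape)
                self._slices.append(sl)
                off += n
        self._m = np.zeros(total, dtype=np.float32)
        self._v = np.zeros(total, dtype=np.float32)
        self._g = np.zeros(total, dtype=np.float32)

    def zero_grad(self) -> None:
        for p in self._params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        g = self._g
        g[:] = 0.0
        for p, sl in zip(self._params, self._slices):
            if p.grad is not None:
                g[sl] = p.grad.ravel()
        if self.clip_grad_norm is not None:
            norm = float(np.sqrt((g.astype(np.float64) ** 2).sum()))
            if norm > self.clip_grad_norm:
                g *= np.float32(self.clip_grad_norm / (norm + 1e-12))
        m, v, flat = self._m, self._v, self._flat
        m *= b1; m += np.float32(1 - b1) * g
        v *= b2; v += np.float32(1 - b2) * g * g
        bc1 = np.float32(1.0 - b1 ** self.t)
        bc2 = np.float32(1.0 - b2 ** self.t)
        upd = (m / bc1) / (np.sqrt(v / bc2) + np.float32(self.eps))
        upd += np.float32(self.weight_decay) * flat
        flat -= self.lr * self._lr_scale * upd


# -- positional encodings and interpolation --------------------------

@lru_cache(maxsize=64)
def sinusoidal_position_encoding(H: int, W: int, dim: int,
                                 temperature: float = 10000.0) -> np.ndarray:
    """2-D sinusoidal embedding, shape (H*W, dim); dim divisible by 4."""
    if dim % 4 != 0:
        raise ValueError("positional encoding dim must be divisible by 4")
    d = dim // 4
    omega = 1.0 / temperature ** (np.arange(d) / d)
    ys, xs = np.meshgrid(np.arange(H, dtype=np.float64),
                         np.arange(W, dtype=np.float64), indexing="ij")
    out = np.concatenate([
        np.sin(ys.reshape(-1, 1) * omega), np.cos(ys.reshape(-1, 1) * omega),
        np.sin(xs.reshape(-1, 1) * omega), np.cos(xs.reshape(-1, 1) * omega),
    ], axis=1)
    return out.astype(np.float32)


def _keys_cubic(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (the classical bicubic, a = -1/2)."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


@lru_cache(maxsize=256)
def resize_matrix(n_out: int, n_in: int, kind: str = "bilinear") -> np.ndarray:
    """Dense 1-D resampling matrix A (n_out × n_in), half-pixel centers.

    Out-of-range taps clamp to the edge sample (replicate padding), so
    rows always sum to 1 and constants are reproduced exactly.
    """
    A = np.zeros((n_out, n_in), dtype=np.float64)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        if kind == "bilinear":
            lo = int(np.floor(src))
            taps = np.arange(lo, lo + 2)
            w = np.array([1.0 - (src - lo), src - lo])
        elif kind == "bicubic":
            lo = int(np.floor(src)) - 1
            taps = np.arange(lo, lo + 4)
            w = _keys_cubic(src - taps)
        elif kind == "nearest":
            taps = np.array([int(np.floor(src + 0.5)) if n_out < n_in
                             else int(np.round(src))])
            taps = np.clip(taps, 0, n_in - 1)
            w = np.array([1.0])
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")
        taps = np.clip(taps, 0, n_in - 1)
        np.add.at(A[i], taps, w)
    return A.astype(np.float32)


def resize_map(x: Tensor, h_out: int, w_out: int, kind: str = "bilinear") -> Tensor:
    """Differentiable resize of a (C, H, W) feature map via matmuls."""
    C, H, W = x.shape
    Ah = Tensor(resize_matrix(h_out, H, kind))
    Aw = Tensor(resize_matrix(w_out, W, kind))
    y = matmul(Ah, x)                       # (C, h_out, W) via broadcast
    y = matmul(y, Aw.data.T)
    return y


def resize_map_np(x: np.ndarray, h_out: int, w_out: int,
                  kind: str = "bilinear") -> np.ndarray:
    """Plain-numpy resize (same matrices) for detached arrays like masks."""
    Ah = resize_matrix(h_out, x.shape[-2], kind)
    Aw = resize_matrix(w_out, x.shape[-1], kind)
    return np.einsum("hH,...HW,wW->...hw", Ah, x.astype(np.float32), Aw,
                     optimize=True)
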