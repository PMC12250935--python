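"""Hierarchical encoder: patch embedding plus a four-stage dilated
neighborhood-attention backbone.

The backbone follows the DiNAT recipe: an initial two-step strided
projection brings the image to 1/4 resolution (f0), then four stages of
transformer blocks whose attention is restricted to a k x k neighborhood
around each position, alternating dilation 1 with the stage's maximum
feasible dilation to widen the field of view.  Between stages the spatial
size halves and the channel count doubles, yielding features f4, f8, f16,
f32 at 1/4, 1/8, 1/16 and 1/32 of the padded input with embed_dim x
{1, 2, 4, 8} channels.

Border handling: neighborhoods are clamped (shifted inward) so every
query attends to exactly k^2 valid positions; keys are never zero-padded.
This changes outputs near borders relative to a zero-padding convention
and is the convention the brute-force test oracle implements as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._autodiff import Tensor, gelu, reshape, softmax, take_rows, transpose
from .core_io import RunConfig
from .nn import Conv2d, LayerNorm, Linear, Mlp, Module, Parameter

__all__ = ["FeaturePyramid", "PatchEmbed", "NeighborhoodAttention",
           "EncoderBlock", "EncoderStage", "Encoder", "na_indices",
           "max_feasible_dilation"]


@dataclass
class FeaturePyramid:
    """Named multi-scale features with strict shape contracts.

    f-levels come from the encoder (embed_dim x {1,2,4,8} channels),
    p-levels from the pixel decoder, v/g-levels from the cross-scale
    guidance module (all decoder_dim channels).  Maps are (C, H, W).
    """

    f4: Tensor | None = None
    f8: Tensor | None = None
    f16: Tensor | None = None
    f32: Tensor | None = None
    p4: Tensor | None = None
    p8: Tensor | None = None
    p16: Tensor | None = None
    p32: Tensor | None = None
    v4: Tensor | None = None
    v8: Tensor | None = None
    v16: Tensor | None = None
    g4: Tensor | None = None
    g8: Tensor | None = None
    g16: Tensor | None = None

    def check_encoder_contract(self, H: int, W: int, embed_dim: int) -> None:
        for name, s, mult in (("f4", 4, 1), ("f8", 8, 2),
                              ("f16", 16, 4), ("f32", 32, 8)):
            t = getattr(self, name)
            if t is None:
                raise ValueError(f"{name} missing")
            c, h, w = t.shape
            if (h, w) != (H // s, W // s) or c != embed_dim * mult:
                raise ValueError(
                    f"{name} shape {t.shape} violates the scale contract "
                    f"for input {H}x{W}, embed_dim {embed_dim}")


def max_feasible_dilation(H: int, W: int, kernel: int) -> int:
    """Largest dilation for which a k x k neighborhood with spacing delta
    still fits inside an H x W map."""
    if kernel == 1:
        return 1
    return max(1, (min(H, W) - 1) // (kernel - 1))


@lru_cache(maxsize=256)
def na_indices(H: int, W: int, kernel: int, dilation: int) -> np.ndarray:
    """Flat token indices of each position's clamped k x k neighborhood.

    Returns an (H*W, k*k) int array.  The window anchor is shifted inward
    at borders so all k^2 positions are valid and spaced by ``dilation``.
    """
    span = dilation * (kernel - 1)
    if span > H - 1 or span > W - 1:
        raise ValueError(
            f"{kernel}x{kernel} neighborhood with dilation {dilation} "
            f"cannot fit in a {H}x{W} map")
    half = kernel // 2
    iy = np.arange(H)
    ix = np.arange(W)
    ay = np.clip(iy - dilation * half, 0, H - 1 - span)
    ax = np.clip(ix - dilation * half, 0, W - 1 - span)
    off = dilation * np.arange(kernel)
    wy = ay[:, None] + off[None, :]            # (H, k)
    wx = ax[:, None] + off[None, :]            # (W, k)
    rows = wy[:, None, :, None] * W + wx[None, :, None, :]  # (H, W, k, k)
    return rows.reshape(H * W, kernel * kernel)


class NeighborhoodAttention(Module):
    """Multi-head attention over a local (optionally dilated) window.

    Operates on token arrays of shape (H*W, C); returns the attention
    output (no residual).  A learnable bias indexed by window slot plays
    the role of the relative-position bias.
    """

    def __init__(self, dim: int, n_heads: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        if dim % n_heads != 0:
            raise ValueError("dim must divide evenly into heads")
        self.dim = dim
        self.n_heads = n_heads
        self.kernel = kernel
        self.dilation = dilation
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.rel_bias = Parameter(np.zeros((n_heads, kernel * kernel),
                                           dtype=np.float32))

    def __call__(self, x: Tensor, H: int, W: int) -> Tensor:
        k2 = self.kernel * self.kernel
        h, dh = self.n_heads, self.dim // self.n_heads
        idx = na_indices(H, W, self.kernel, self.dilation)
        qkv = self.qkv(x).reshape(H * W, 3, h, dh)
        q = qkv[:, 0] * np.float32(dh ** -0.5)          # (HW, h, dh)
        kk = qkv[:, 1]
        vv = qkv[:, 2]
        kn = take_rows(kk, idx)                          # (HW, k2, h, dh)
        vn = take_rows(vv, idx)
        logits = (reshape(q, (H * W, 1, h, dh)) * kn).sum(axis=3)  # (HW, k2, h)
        bk = int(round(np.sqrt(self.rel_bias.shape[1])))
        if self.kernel != bk:  # runtime-shrunk window: top-left bias block
            bias = self.rel_bias.reshape(h, bk, bk)[:, :self.kernel,
                                                    :self.kernel]
            bias = bias.reshape(h, k2)
        else:
            bias = self.rel_bias
        logits = logits + transpose(bias, (1, 0))                  # (k2, h)
        attn = softmax(logits, axis=1)
        out = (reshape(attn, (H * W, k2, h, 1)) * vn).sum(axis=1)  # (HW, h, dh)
        return self.proj(out.reshape(H * W, self.dim))


class EncoderBlock(Module):
    """Pre-norm transformer block: neighborhood attention + MLP."""

    def __init__(self, dim: int, n_heads: int, kernel: int, dilation: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = NeighborhoodAttention(dim, n_heads, kernel, dilation, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor, H: int, W: int) -> Tensor:
        x = x + self.attn(self.norm1(x), H, W)
        x = x + self.mlp(self.norm2(x))
        return x


class Downsample(Module):
    """Stride-2 3x3 convolution doubling the channels, then LayerNorm."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv = Conv2d(dim, 2 * dim, 3, rng, stride=2, padding=1)
        self.norm = LayerNorm(2 * dim)

    def __call__(self, x: Tensor, H: int, W: int) -> tuple[Tensor, int, int]:
        if H % 2 or W % 2:
            raise ValueError(f"cannot downsample odd spatial dims {H}x{W}")
        m = transpose(x.reshape(H, W, -1), (2, 0, 1))
        y = self.conv(m)
        C2, H2, W2 = y.shape
        tokens = transpose(y, (1, 2, 0)).reshape(H2 * W2, C2)
        return self.norm(tokens), H2, W2


class PatchEmbed(Module):
    """Two stride-2 local projections: image -> 1/4-scale f0 tokens."""

    def __init__(self, in_channels: int, embed_dim: int,
                 rng: np.random.Generator):
        mid = max(embed_dim // 2, 1)
        self.conv1 = Conv2d(in_channels, mid, 3, rng, stride=2, padding=1)
        self.conv2 = Conv2d(mid, embed_dim, 3, rng, stride=2, padding=1)
        self.norm = LayerNorm(embed_dim)
        self.embed_dim = embed_dim

    def __call__(self, img: Tensor) -> tuple[Tensor, int, int]:
        """img: (C, H, W), H and W divisible by 4 -> tokens (HW/16, D)."""
        _, H, W = img.shape
        if H % 4 or W % 4:
            raise ValueError("input dims must be divisible by 4 (pad first)")
        y = self.conv2(gelu(self.conv1(img)))
        D, H4, W4 = y.shape
        tokens = transpose(y, (1, 2, 0)).reshape(H4 * W4, D)
        return self.norm(tokens), H4, W4


class EncoderStage(Module):
    """``depth`` blocks alternating dilation 1 / stage max dilation."""

    def __init__(self, dim: int, depth: int, n_heads: int, kernel: int,
                 max_dilation: int, mlp_ratio: float,
                 rng: np.random.Generator):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.max_dilation = max_dilation
        self.kernel = kernel
        self.blocks = [
            EncoderBlock(dim, n_heads, kernel,
                         1 if i % 2 == 0 else max_dilation, mlp_ratio, rng)
            for i in range(depth)
        ]

    def __call__(self, x: Tensor, H: int, W: int) -> Tensor:
        feasible = max_feasible_dilation(H, W, self.kernel)
        for blk in self.blocks:
            want_d = min(blk.attn.dilation, feasible)
            want_k = self.kernel
            if (want_k - 1) * want_d > min(H, W) - 1:
                # map smaller than the window: fall back to attention
                # over the whole map (window = map extent)
                want_k, want_d = min(H, W), 1
            if want_d != blk.attn.dilation or want_k != blk.attn.kernel:
                blk = _with_window(blk, want_k, want_d)
            x = blk(x, H, W)
        return x


def _with_window(block: EncoderBlock, kernel: int, dilation: int
                 ) -> EncoderBlock:
    """Shallow view of a block with a clamped runtime window."""
    clone = EncoderBlock.__new__(EncoderBlock)
    clone.__dict__.update(block.__dict__)
    attn = NeighborhoodAttention.__new__(NeighborhoodAttention)
    attn.__dict__.update(block.attn.__dict__)
    attn.kernel = kernel
    attn.dilation = dilation
    clone.attn = attn
    return clone


class Encoder(Module):
    """Patch embedding plus four stages emitting f4, f8, f16, f32."""

    def __init__(self, config: RunConfig, rng: np.random.Generator,
                 in_channels: int = 3):
        D = config.embed_dim
        self.config = config
        self.patch_embed = PatchEmbed(in_channels, D, rng)
        self.stages = []
        self.downsamples = []
        for s in range(config.n_stages):
            dim = D * (2 ** s)
            self.stages.append(EncoderStage(
                dim, config.depths[s], config.n_heads[s], config.na_kernel,
                config.na_dilations[s], config.mlp_ratio, rng))
            if s < config.n_stages - 1:
                self.downsamples.append(Downsample(dim, rng))

    def __call__(self, img: Tensor) -> FeaturePyramid:
        tokens, H, W = self.patch_embed(img)
        pyr = FeaturePyramid()
        names = ("f4", "f8", "f16", "f32")
        for s, stage in enumerate(self.stages):
            tokens = stage(tokens, H, W)
            fmap = transpose(tokens.reshape(H, W, -1), (2, 0, 1))
            setattr(pyr, names[s], fmap)
            if s < len(self.downsamples):
                tokens, H, W = self.downsamples[s](tokens, H, W)
        return pyr
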