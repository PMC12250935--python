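"""Pixel decoder: multi-scale deformable attention over the 1/8, 1/16
and 1/32 encoder features, plus a lateral upsampling path for 1/4.

Each deformable layer lets every feature position (a "query") sample a
small set of learned offset locations from every pyramid level by
bilinear interpolation and combine them with softmax-normalized learned
weights — attention without the quadratic cost.  Sinusoidal positional
encodings and a learnable per-level embedding are added to the queries.
The 1/4-scale output p4 is formed by projecting f4 laterally and adding
the upsampled p8, followed by a 3x3 fusion convolution.

All p-levels have decoder_dim channels.  Bilinear sampling uses the
half-pixel-center convention; sample coordinates are clamped to the
valid normalized range.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, clip, concat, reshape, softmax, take_rows, transpose
from .core_io import RunConfig
from .encoder import FeaturePyramid
from .nn import (Conv2d, LayerNorm, Linear, Mlp, Module, Parameter,
                 resize_map, sinusoidal_position_encoding)

__all__ = ["MSDeformAttention", "DeformableLayer", "PixelDecoder",
           "bilinear_sample_tokens", "lateral_upsample"]


def bilinear_sample_tokens(v_flat: Tensor, H: int, W: int, n_heads: int,
                           px: Tensor, py: Tensor) -> Tensor:
    """Differentiable bilinear sampling from per-head token values.

    v_flat: (H*W*n_heads, dh) — row ``(y*W + x)*n_heads + h`` holds the
    value of position (y, x) for head h.  px, py: pixel coordinates of
    shape (S, n_heads, P); gradients flow to both values and coordinates.
    Out-of-range coordinates clamp to the border pixel.
    """
    px = clip(px, 0.0, max(W - 1, 0))
    py = clip(py, 0.0, max(H - 1, 0))
    x0 = np.floor(px.data).astype(np.int64)
    y0 = np.floor(py.data).astype(np.int64)
    x0 = np.clip(x0, 0, max(W - 2, 0))
    y0 = np.clip(y0, 0, max(H - 2, 0))
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = clip(px - Tensor(x0.astype(np.float32)), 0.0, 1.0)
    fy = clip(py - Tensor(y0.astype(np.float32)), 0.0, 1.0)
    head = np.arange(n_heads, dtype=np.int64)[None, :, None]

    def gather(yy, xx):
        rows = (yy * W + xx) * n_heads + head
        return take_rows(v_flat, rows)          # (S, h, P, dh)

    one = 1.0
    wa = ((one - fy) * (one - fx)).reshape(*fx.shape, 1)
    wb = ((one - fy) * fx).reshape(*fx.shape, 1)
    wc = (fy * (one - fx)).reshape(*fx.shape, 1)
    wd = (fy * fx).reshape(*fx.shape, 1)
    return (wa * gather(y0, x0) + wb * gather(y0, x1)
            + wc * gather(y1, x0) + wd * gather(y1, x1))


class MSDeformAttention(Module):
    """Multi-scale deformable attention over L pyramid levels.

    For each query (a position in any level) and each head, ``n_points``
    offset locations are sampled from every level; their values are
    combined with weights softmax-normalized across (levels x points).
    """

    def __init__(self, dim: int, n_heads: int, n_points: int, n_levels: int,
                 rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must divide into heads")
        self.dim, self.n_heads, self.n_points, self.n_levels = \
            dim, n_heads, n_points, n_levels
        self.value_proj = Linear(dim, dim, rng)
        self.output_proj = Linear(dim, dim, rng)
        self.offset_proj = Linear(dim, n_heads * n_levels * n_points * 2, rng)
        self.weight_proj = Linear(dim, n_heads * n_levels * n_points, rng)
        # grid initialization: zero offset weights, per-head directional bias
        self.offset_proj.weight.data[:] = 0.0
        self.weight_proj.weight.data[:] = 0.0
        self.weight_proj.bias.data[:] = 0.0
        thetas = 2.0 * np.pi * np.arange(n_heads) / n_heads
        grid = np.stack([np.cos(thetas), np.sin(thetas)], axis=-1)  # (h, 2)
        grid = grid / np.abs(grid).max(axis=-1, keepdims=True)
        bias = np.tile(grid[:, None, None, :], (1, n_levels, n_points, 1))
        bias = bias * (np.arange(n_points) + 1.0)[None, None, :, None]
        self.offset_proj.bias.data = bias.reshape(-1).astype(np.float32)

    def __call__(self, query: Tensor, value_tokens: list[Tensor],
                 shapes: list[tuple[int, int]],
                 ref_points: np.ndarray) -> Tensor:
        """query: (S, D); value_tokens[l]: (H_l*W_l, D); ref_points:
        constant (S, 2) normalized (x, y) reference per query."""
        S = query.shape[0]
        h, P, L, D = self.n_heads, self.n_points, self.n_levels, self.dim
        dh = D // h
        offsets = self.offset_proj(query).reshape(S, h, L, P, 2)
        weights = softmax(self.weight_proj(query).reshape(S, h, L * P), axis=2)
        weights = weights.reshape(S, h, L, P)
        out = None
        ref = ref_points.astype(np.float32)  # (S, 2) in [0,1]
        for lvl, (tok, (H, W)) in enumerate(zip(value_tokens, shapes)):
            v = self.value_proj(tok).reshape(H * W, h, dh)
            v_flat = v.reshape(H * W * h, dh)
            # normalized sample location = ref + offset / level size
            ox = offsets[:, :, lvl, :, 0] * np.float32(1.0 / W)
            oy = offsets[:, :, lvl, :, 1] * np.float32(1.0 / H)
            locx = clip(ox + Tensor(ref[:, None, None, 0]), 0.0, 1.0)
            locy = clip(oy + Tensor(ref[:, None, None, 1]), 0.0, 1.0)
            px = locx * np.float32(W) - np.float32(0.5)
            py = locy * np.float32(H) - np.float32(0.5)
            samp = bilinear_sample_tokens(v_flat, H, W, h, px, py)  # (S,h,P,dh)
            w = weights[:, :, lvl].reshape(S, h, P, 1)
            contrib = (w * samp).sum(axis=2)                        # (S,h,dh)
            out = contrib if out is None else out + contrib
        return self.output_proj(out.reshape(S, D))


class DeformableLayer(Module):
    """Pre-norm deformable attention + feed-forward block."""

    def __init__(self, dim: int, n_heads: int, n_points: int, n_levels: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MSDeformAttention(dim, n_heads, n_points, n_levels, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor, splits, shapes, ref, pos) -> Tensor:
        q = self.norm1(x) + pos
        vals = [q[lo:hi] for lo, hi in splits]
        x = x + self.attn(q, vals, shapes, ref)
        x = x + self.mlp(self.norm2(x))
        return x


def lateral_upsample(p8: Tensor, f4_proj: Tensor, fuse_conv: Conv2d) -> Tensor:
    """p4 = fuse3x3(project(f4) + upsample_x2(p8)); all at decoder_dim."""
    _, H8, W8 = p8.shape
    up = resize_map(p8, 2 * H8, 2 * W8, "bilinear")
    return fuse_conv(f4_proj + up)


class PixelDecoder(Module):
    """Produces p4, p8, p16, p32 (decoder_dim channels) from f4..f32."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        D = config.decoder_dim
        E = config.embed_dim
        self.config = config
        self.proj8 = Linear(2 * E, D, rng)
        self.proj16 = Linear(4 * E, D, rng)
        self.proj32 = Linear(8 * E, D, rng)
        self.norm8 = LayerNorm(D)
        self.norm16 = LayerNorm(D)
        self.norm32 = LayerNorm(D)
        self.level_embed = Parameter(np.zeros((3, D), dtype=np.float32))
        self.layers = [
            DeformableLayer(D, config.n_deform_heads, config.n_deform_points,
                            3, config.mlp_ratio, rng)
            for _ in range(config.n_deform_layers)
        ]
        self.proj4 = Linear(E, D, rng)
        self.norm4 = LayerNorm(D)
        self.fuse_conv = Conv2d(D, D, 3, rng, padding=1)

    @staticmethod
    def _tokens(fmap: Tensor) -> tuple[Tensor, int, int]:
        C, H, W = fmap.shape
        return transpose(fmap, (1, 2, 0)).reshape(H * W, C), H, W

    def __call__(self, pyr: FeaturePyramid) -> FeaturePyramid:
        D = self.config.decoder_dim
        t8, H8, W8 = self._tokens(pyr.f8)
        t16, H16, W16 = self._tokens(pyr.f16)
        t32, H32, W32 = self._tokens(pyr.f32)
        toks = [self.norm8(self.proj8(t8)),
                self.norm16(self.proj16(t16)),
                self.norm32(self.proj32(t32))]
        shapes = [(H8, W8), (H16, W16), (H32, W32)]
        sizes = [H * W for H, W in shapes]
        splits = []
        lo = 0
        for s in sizes:
            splits.append((lo, lo + s))
            lo += s
        x = concat(toks, axis=0)

        # constant per-query additions: sinusoidal position + level embed
        pos_np = np.concatenate([
            sinusoidal_position_encoding(H, W, D) for (H, W) in shapes], axis=0)
        if not self.config.use_positional_encoding:
            pos_np = np.zeros_like(pos_np)
        lvl = concat([self.level_embed[i:i + 1].reshape(1, D) * np.ones((s, 1), np.float32)
                      for i, s in enumerate(sizes)], axis=0)
        pos = Tensor(pos_np) + lvl

        refs = []
        for (H, W) in shapes:
            ys, xs = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            refs.append(np.stack([(xs.ravel() + 0.5) / W,
                                  (ys.ravel() + 0.5) / H], axis=1))
        ref = np.concatenate(refs, axis=0)

        for layer in self.layers:
            x = layer(x, splits, shapes, ref, pos)

        def to_map(tokens: Tensor, H: int, W: int) -> Tensor:
            return transpose(tokens.reshape(H, W, D), (2, 0, 1))

        pyr.p8 = to_map(x[splits[0][0]:splits[0][1]], H8, W8)
        pyr.p16 = to_map(x[splits[1][0]:splits[1][1]], H16, W16)
        pyr.p32 = to_map(x[splits[2][0]:splits[2][1]], H32, W32)

        t4, H4, W4 = self._tokens(pyr.f4)
        f4p = to_map(self.norm4(self.proj4(t4)), H4, W4)
        pyr.p4 = lateral_upsample(pyr.p8, f4p, self.fuse_conv)
        return pyr
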