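"""Cross-scale guidance integration: inject the coarsest, largest
field-of-view features into every finer scale, then fuse across scales.

Block 1 (guidance): the 1/32 feature map p32 is enlarged by bicubic
interpolation with scale factors 2, 4 and 8, concatenated channelwise
with p16, p8 and p4 respectively, and projected back to decoder_dim
channels by a single 1x1 convolution whose weights are *shared* across
the three scales:

    v_k = conv1( U^j(p32) (+)concat p_k ),   k = 32/j,  j in {2, 4, 8}

Block 2 (fusion): v16 — the remaining coarsest guidance feature — is
upsampled and used as a multiplicative weight map on the finer scales,
with a residual so zero guidance leaves the feature untouched:

    g_k = U^j(v16) * v_k + v_k,   k = 16/j,  j in {2, 4};   g16 = v16

The weight map is used raw (no squashing): plain elementwise
multiplication followed by addition.  An optional ``gated`` switch
applies a sigmoid to the weight map but is off by default.  The 1x1
projection carries a bias; no nonlinearity or normalization follows it.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, sigmoid, transpose
from .core_io import RunConfig
from .encoder import FeaturePyramid
from .nn import Linear, Module, resize_map

__all__ = ["upsample_bicubic", "GuidanceBlock", "CrossScaleGuidance"]


def upsample_bicubic(x: Tensor, j: int) -> Tensor:
    """Enlarge a (C, H, W) map by integer factor j with Keys bicubic
    interpolation (a = -1/2), half-pixel centers, replicate borders."""
    if j < 1:
        raise ValueError("scale factor must be a positive integer")
    _, H, W = x.shape
    return resize_map(x, H * j, W * j, "bicubic")


class GuidanceBlock(Module):
    """Shared-weight 1x1 projection of concat(U^j(p32), p_k) -> v_k."""

    def __init__(self, dim: int, rng: np.random.Generator):
        # one parameter set serves all three scales
        self.conv1 = Linear(2 * dim, dim, rng, bias=True)
        self.dim = dim

    def __call__(self, p32: Tensor, pk: Tensor, j: int) -> Tensor:
        up = upsample_bicubic(p32, j)
        if up.shape[1:] != pk.shape[1:]:
            raise ValueError(
                f"U^{j}(p32) spatial {up.shape[1:]} does not match p_k {pk.shape[1:]}")
        if up.shape[0] != pk.shape[0]:
            raise ValueError("channel mismatch between p32 and p_k")
        cat = concat([up, pk], axis=0)                    # (2C, H, W)
        C2, H, W = cat.shape
        tokens = transpose(cat, (1, 2, 0)).reshape(H * W, C2)
        out = self.conv1(tokens)
        return transpose(out.reshape(H, W, self.dim), (2, 0, 1))


class CrossScaleGuidance(Module):
    """Both blocks; fills v4, v8, v16 and g4, g8, g16 of the pyramid."""

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        self.guidance = GuidanceBlock(config.decoder_dim, rng)
        self.gated = config.gated_guidance

    def fuse(self, v16: Tensor, vk: Tensor, j: int) -> Tensor:
        """g_k = U^j(v16) * v_k + v_k (elementwise)."""
        w = upsample_bicubic(v16, j)
        if w.shape != vk.shape:
            raise ValueError(f"shape mismatch after upsampling: "
                             f"{w.shape} vs {vk.shape}")
        if self.gated:
            w = sigmoid(w)
        return w * vk + vk

    def __call__(self, pyr: FeaturePyramid) -> FeaturePyramid:
        pyr.v16 = self.guidance(pyr.p32, pyr.p16, 2)
        pyr.v8 = self.guidance(pyr.p32, pyr.p8, 4)
        pyr.v4 = self.guidance(pyr.p32, pyr.p4, 8)
        pyr.g16 = pyr.v16  # no computation, by definition
        pyr.g8 = self.fuse(pyr.v16, pyr.v8, 2)
        pyr.g4 = self.fuse(pyr.v16, pyr.v4, 4)
        return pyr
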