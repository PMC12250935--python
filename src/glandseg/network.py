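"""End-to-end network: encoder -> pixel decoder -> cross-scale guidance
-> masked-attention decoder, with checkpoint save/load."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ._autodiff import Tensor
from .core_io import RunConfig
from .csgi import CrossScaleGuidance
from .encoder import Encoder, FeaturePyramid
from .mask_decoder import MaskDecoder, QueryState
from .nn import Module
from .pixel_decoder import PixelDecoder

__all__ = ["SegmentationNetwork"]

CHECKPOINT_VERSION = 1


class SegmentationNetwork(Module):
    """The full instance segmentation network.

    ``forward`` consumes a pre-padded float image (H, W, C) with H, W
    divisible by 32 and returns the feature pyramid plus the per-layer
    query state (mask and class logits at 1/4 scale).
    """

    def __init__(self, config: RunConfig, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.pixel_decoder = PixelDecoder(config, rng)
        self.csgi = CrossScaleGuidance(config, rng)
        self.mask_decoder = MaskDecoder(config, rng)

    def normalize(self, pixels: np.ndarray) -> np.ndarray:
        mean = np.asarray(self.config.normalize_mean, dtype=np.float32)
        std = np.asarray(self.config.normalize_std, dtype=np.float32)
        c = pixels.shape[2]
        return (pixels - mean[:c]) / std[:c]

    def forward(self, pixels: np.ndarray) -> tuple[FeaturePyramid, QueryState]:
        """pixels: (H, W, C) float in [0, 1], dims divisible by 32."""
        H, W = pixels.shape[:2]
        if H % 32 or W % 32:
            raise ValueError("network input dims must be divisible by 32")
        img = Tensor(np.ascontiguousarray(
            self.normalize(pixels).transpose(2, 0, 1)))
        pyr = self.encoder(img)
        pyr.check_encoder_contract(H, W, self.config.embed_dim)
        pyr = self.pixel_decoder(pyr)
        pyr = self.csgi(pyr)
        state = self.mask_decoder(pyr)
        return pyr, state

    __call__ = forward

    def backbone_parameters(self):
        return self.encoder.parameters()

    def head_parameters(self):
        bb = {id(p) for p in self.encoder.parameters()}
        return [p for p in self.parameters() if id(p) not in bb]

    # -- checkpointing -------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        import dataclasses
        import json
        state = self.state_dict()
        meta = json.dumps({
            "version": CHECKPOINT_VERSION,
            "config": dataclasses.asdict(self.config),
        }, default=list)
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "SegmentationNetwork":
        import json
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            cfg_d = meta["config"]
            for k, v in cfg_d.items():
                if isinstance(v, list):
                    cfg_d[k] = tuple(v)
            config = RunConfig(**cfg_d)
            net = cls(config)
            net.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        return net
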