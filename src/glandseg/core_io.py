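"""Domain types and I/O: image tiles, instance label maps, run config.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* images live in memory as float32 ``(H, W, C)`` arrays in ``[0, 1]``;
* instance label maps are integer ``(H, W)`` arrays where 0 is background
  and labels ``1..n_objects`` form a contiguous set, each owning at least
  one pixel — glands are mutually exclusive, a pixel belongs to exactly
  one instance;
* label maps are stored on disk as single-channel 16-bit PNG (a separate
  debug writer produces color-coded overlays, which are never parsed back);
* every scale-``s`` feature map is aligned to the full image with
  half-pixel centers, matching standard resize semantics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "ImageTile", "InstanceLabelMap", "PadRecord", "RunConfig",
    "read_image", "write_image", "read_instance_map", "write_instance_map",
    "write_color_overlay", "pad_to_multiple", "crop_back", "relabel_contiguous",
]


@dataclass
class ImageTile:
    """An RGB(A)/gray pathology tile with intensities in [0, 1]."""

    pixels: np.ndarray  # (H, W, C) float32 in [0, 1]
    id: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim == 2:
            p = p[:, :, None]
        if p.ndim != 3:
            raise ValueError("ImageTile.pixels must be (H, W, C)")
        if p.shape[2] < 1:
            raise ValueError("ImageTile needs at least one channel")
        self.pixels = p.astype(np.float32)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class InstanceLabelMap:
    """Integer instance map: 0 = background, k >= 1 = object k."""

    labels: np.ndarray  # (H, W) int32
    n_objects: int = -1

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(np.int32)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.n_objects < 0:
            self.n_objects = int(self.labels.max(initial=0))
        self.validate()

    def validate(self) -> None:
        present = np.unique(self.labels)
        if present.min(initial=0) < 0:
            raise ValueError("negative labels are not allowed")
        expected = np.arange(1, self.n_objects + 1)
        fg = present[present > 0]
        if not np.array_equal(fg, expected):
            raise ValueError(
                f"labels must be contiguous 1..{self.n_objects}, got {fg.tolist()[:10]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def object_mask(self, k: int) -> np.ndarray:
        return self.labels == k


@dataclass(frozen=True)
class PadRecord:
    """Amount of reflective padding applied; allows exact crop-back."""

    orig_h: int
    orig_w: int
    top: int
    left: int


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary non-negative labels onto {0, 1, .., K} preserving
    distinctness and background; ordering follows ascending old label."""
    labels = np.asarray(labels)
    vals = np.unique(labels)
    lut = np.zeros(int(vals.max(initial=0)) + 1, dtype=np.int32)
    nxt = 1
    for v in vals:
        if v == 0:
            continue
        lut[v] = nxt
        nxt += 1
    return lut[labels]


# -- readers / writers ------------------------------------------------

def read_image(path: str | Path) -> ImageTile:
    """Read a PNG/BMP/TIFF tile into float [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode not in ("RGB", "L", "RGBA"):
        img = img.convert("RGB")
    arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return ImageTile(arr.astype(np.float32) / 255.0, id=path.stem)


def write_image(path: str | Path, tile: ImageTile) -> None:
    arr = np.clip(tile.pixels, 0.0, 1.0)
    arr = (arr * 255.0 + 0.5).astype(np.uint8)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    Image.fromarray(arr).save(path)


def read_instance_map(path: str | Path) -> InstanceLabelMap:
    """Read a single-channel 8/16-bit PNG instance map.

    Values are relabeled to a contiguous 0..K set preserving distinctness.
    Multi-channel (color-coded) inputs are rejected: the color-to-instance
    palette of such visualizations is ambiguous.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = Image.open(path)
    if img.mode in ("I;16", "I;16B"):
        arr = np.asarray(img, dtype=np.uint16)
    elif img.mode in ("I", "L", "P"):
        arr = np.asarray(img.convert("I"))
    else:
        raise ValueError(
            f"{path}: instance maps must be single-channel PNG, got mode {img.mode!r} "
            "(color-coded maps need an explicit palette and are not supported)")
    labels = relabel_contiguous(np.asarray(arr).astype(np.int64))
    return InstanceLabelMap(labels)


def write_instance_map(path: str | Path, imap: InstanceLabelMap) -> None:
    """Write as 16-bit single-channel PNG; round-trips bit-exactly for
    label counts up to 65535."""
    if imap.n_objects > 65535:
        raise ValueError("16-bit PNG supports at most 65535 instances")
    arr = imap.labels.astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path, format="PNG")


def write_color_overlay(path: str | Path, tile: ImageTile,
                        imap: InstanceLabelMap, alpha: float = 0.45) -> None:
    """Debug writer: random-colored instances blended over the tile."""
    rng = np.random.default_rng(12345)
    colors = rng.uniform(0.15, 1.0, size=(max(imap.n_objects, 1) + 1, 3))
    colors[0] = 0.0
    overlay = colors[np.clip(imap.labels, 0, imap.n_objects)]
    base = tile.pixels[:, :, :3] if tile.channels >= 3 else np.repeat(tile.pixels, 3, axis=2)
    fg = (imap.labels > 0)[:, :, None]
    out = np.where(fg, (1 - alpha) * base + alpha * overlay, base)
    write_image(path, ImageTile(out.astype(np.float32)))


# -- padding ----------------------------------------------------------

def _pad_1d(n: int, m: int) -> int:
    return (-n) % m


def pad_to_multiple(tile: ImageTile, m: int) -> tuple[ImageTile, PadRecord]:
    """Reflect-pad so both spatial dims are the smallest multiples of m.

    Padding goes to the bottom/right; a :class:`PadRecord` allows exact
    crop-back of any full-resolution prediction.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    H, W = tile.height, tile.width
    ph, pw = _pad_1d(H, m), _pad_1d(W, m)
    if ph == 0 and pw == 0:
        return tile, PadRecord(H, W, 0, 0)
    mode = "reflect" if (ph < H and pw < W and min(H, W) > 1) else "edge"
    pixels = np.pad(tile.pixels, ((0, ph), (0, pw), (0, 0)), mode=mode)
    return ImageTile(pixels, id=tile.id), PadRecord(H, W, 0, 0)


def crop_back(arr: np.ndarray, rec: PadRecord) -> np.ndarray:
    """Inverse of :func:`pad_to_multiple` on any (H, W, ...) array."""
    return arr[rec.top:rec.top + rec.orig_h, rec.left:rec.left + rec.orig_w]


# -- run configuration ------------------------------------------------

@dataclass
class RunConfig:
    """All tunable knobs of the network and its training run.

    The full preset mirrors the published large-backbone hyperparameters;
    the tiny preset is sized so that CPU training converges in minutes and
    is the configuration exercised by the test-suite.
    """

    # encoder backbone
    embed_dim: int = 192
    n_stages: int = 4
    depths: tuple[int, ...] = (3, 4, 18, 5)
    n_heads: tuple[int, ...] = (6, 12, 24, 48)
    na_kernel: int = 7
    na_dilations: tuple[int, ...] = (8, 4, 2, 1)  # per-stage max dilation
    mlp_ratio: float = 2.0
    # pixel decoder
    decoder_dim: int = 256
    n_deform_layers: int = 6
    n_deform_heads: int = 8
    n_deform_points: int = 4
    # transformer decoder
    n_queries: int = 100
    n_decoder_layers: int = 9
    n_decoder_heads: int = 8
    n_classes: int = 1  # foreground classes; +1 no-object internally
    use_positional_encoding: bool = True
    gated_guidance: bool = False  # sigmoid on the cross-scale weight map
    # losses
    loss_weight_cls: float = 2.0
    loss_weight_bce: float = 5.0
    loss_weight_dice: float = 5.0
    no_object_weight: float = 0.1
    # optimizer
    lr: float = 1e-4
    backbone_lr_scale: float = 0.1
    weight_decay: float = 0.05
    clip_grad_norm: float = 1.0
    lr_warmup_iters: int = 100
    lr_decay_fraction: float = 0.85  # step-decay point as run fraction
    lr_decay_factor: float = 0.1
    # inference
    score_thresh: float = 0.5
    mask_thresh: float = 0.5
    # data
    tile_size: int = 96
    normalize_mean: tuple[float, float, float] = (0.70, 0.55, 0.70)
    normalize_std: tuple[float, float, float] = (0.20, 0.20, 0.20)
    # bookkeeping
    seed: int = 0
    tiny_preset: bool = False

    def __post_init__(self):
        self.depths = tuple(self.depths)
        self.n_heads = tuple(self.n_heads)
        self.na_dilations = tuple(self.na_dilations)
        if self.na_kernel % 2 != 1:
            raise ValueError("na_kernel must be odd")
        if self.n_decoder_layers % 3 != 0:
            raise ValueError("n_decoder_layers must be divisible by 3 "
                             "(one layer per scale per round)")
        for name in ("embed_dim", "decoder_dim", "n_queries", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.depths) != self.n_stages or len(self.n_heads) != self.n_stages:
            raise ValueError("depths / n_heads must have one entry per stage")

    @classmethod
    def tiny(cls, **overrides) -> "RunConfig":
        """CPU-scale preset used throughout the tests."""
        base = dict(
            embed_dim=32, depths=(1, 1, 1, 1), n_heads=(2, 2, 2, 2),
            na_kernel=3, na_dilations=(2, 2, 1, 1), mlp_ratio=2.0,
            decoder_dim=64, n_deform_layers=1, n_deform_heads=2,
            n_deform_points=2, n_queries=20, n_decoder_heads=2,
            tile_size=96, tiny_preset=True,
            # single-tile batches take a larger base step than the
            # published large-batch setting
            lr=5e-4,
        )
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.pop("_preset", None) == "tiny":
            return cls.tiny(**d)
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})

    def config_hash(self) -> str:
        import hashlib
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
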