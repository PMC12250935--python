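"""User-facing modelling objects, statsmodels-style.

:class:`GlandSegmentationModel` binds a training dataset (image tiles
plus instance ground truth) to a :class:`~glandseg.core_io.RunConfig`;
``fit()`` trains the network and returns a
:class:`GlandSegmentationResults` carrying the trained parameters, the
loss trace, and prediction / evaluation / summary methods.

Example
-------
>>> from glandseg import GlandSegmentationModel, RunConfig
>>> model = GlandSegmentationModel.from_synthetic(
...     n_tiles=8, config=RunConfig.tiny(), seed=0)
>>> res = model.fit(iterations=50)
>>> inst = res.predict(model.dataset[0][0])
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from .core_io import (ImageTile, InstanceLabelMap, RunConfig, crop_back,
                      pad_to_multiple)
from .mask_decoder import Instances, postprocess
from .metrics import MetricReport
from .network import SegmentationNetwork
from .synthetic import SynthSpec, generate_dataset
from .training import Trainer, TrainRecord

__all__ = ["GlandSegmentationModel", "GlandSegmentationResults"]


class GlandSegmentationModel:
    """A gland instance segmentation model bound to a training dataset."""

    def __init__(self, dataset: list[tuple[ImageTile, InstanceLabelMap]],
                 config: RunConfig | None = None, augment_fn=None):
        if not dataset:
            raise ValueError("dataset must contain at least one tile")
        self.dataset = dataset
        self.config = config or RunConfig.tiny()
        self.augment_fn = augment_fn

    @classmethod
    def from_synthetic(cls, n_tiles: int, config: RunConfig | None = None,
                       seed: int = 0, spec: SynthSpec | None = None,
                       augment_fn=None) -> "GlandSegmentationModel":
        config = config or RunConfig.tiny()
        spec = spec or SynthSpec(tile_size=config.tile_size, seed=seed)
        return cls(generate_dataset(spec, n_tiles, seed=seed), config,
                   augment_fn=augment_fn)

    @classmethod
    def from_directory(cls, image_dir: str | Path, label_dir: str | Path,
                       config: RunConfig | None = None,
                       augment_fn=None) -> "GlandSegmentationModel":
        from .data_adapters import load_paired_directory
        return cls(load_paired_directory(image_dir, label_dir), config,
                   augment_fn=augment_fn)

    def fit(self, iterations: int = 2000, seed: int | None = None,
            log_every: int = 100, callback=None) -> "GlandSegmentationResults":
        seed = self.config.seed if seed is None else seed
        net = SegmentationNetwork(self.config,
                                  np.random.default_rng(seed))
        trainer = Trainer(net, self.config)
        t0 = time.time()
        trainer.fit(self.dataset, iterations, seed=seed,
                    augment_fn=self.augment_fn, log_every=log_every,
                    callback=callback)
        return GlandSegmentationResults(self, net, trainer.trace,
                                        fit_seconds=time.time() - t0)


class GlandSegmentationResults:
    """Results of a fitted gland segmentation model."""

    def __init__(self, model: GlandSegmentationModel | None,
                 network: SegmentationNetwork,
                 trace: list[TrainRecord], fit_seconds: float = float("nan")):
        self.model = model
        self.network = network
        self.trace = trace
        self.fit_seconds = fit_seconds

    @property
    def config(self) -> RunConfig:
        return self.network.config

    @property
    def loss_trace(self) -> np.ndarray:
        return np.array([r.loss for r in self.trace])

    # -- inference ----------------------------------------------------
    def predict(self, tile: ImageTile, tile_size: int | None = None,
                overlap: int = 32) -> Instances:
        """Pad, run the network, assemble instances, crop back.

        Images larger than ``tile_size`` (when given) are processed as
        overlapping windows whose per-query detections are stitched by
        score with the same conflict-resolution rule used within a
        single window.
        """
        if tile_size is not None and (tile.height > tile_size
                                      or tile.width > tile_size):
            return self._predict_tiled(tile, tile_size, overlap)
        padded, rec = pad_to_multiple(tile, 32)
        _, state = self.network.forward(padded.pixels)
        inst = postprocess(state.final_masks.data, state.final_classes.data,
                           padded.height, padded.width,
                           self.config.score_thresh, self.config.mask_thresh)
        labels = crop_back(inst.label_map.labels, rec)
        from .core_io import relabel_contiguous
        labels = relabel_contiguous(labels)
        imap = InstanceLabelMap(labels)
        kept = int(labels.max(initial=0))
        return Instances(imap, inst.scores[:kept] if kept else [], kept)

    def _predict_tiled(self, tile: ImageTile, tile_size: int,
                       overlap: int) -> Instances:
        """Overlapping-window inference stitched by detection score."""
        from scipy.special import expit
        H, W = tile.height, tile.width
        stride = max(tile_size - overlap, 1)
        ys = sorted({min(y, max(H - tile_size, 0))
                     for y in range(0, H, stride)})
        xs = sorted({min(x, max(W - tile_size, 0))
                     for x in range(0, W, stride)})
        detections: list[tuple[float, int, int, np.ndarray]] = []
        for y0 in ys:
            for x0 in xs:
                win = ImageTile(tile.pixels[y0:y0 + tile_size,
                                            x0:x0 + tile_size])
                padded, rec = pad_to_multiple(win, 32)
                _, state = self.network.forward(padded.pixels)
                cls = state.final_classes.data.astype(np.float64)
                e = np.exp(cls - cls.max(axis=1, keepdims=True))
                fg = 1.0 - (e / e.sum(axis=1, keepdims=True))[:, -1]
                from .nn import resize_map_np
                up = resize_map_np(state.final_masks.data,
                                   padded.height, padded.width, "bilinear")
                probs = expit(up)[:, :win.height, :win.width]
                for q in np.flatnonzero(fg > self.config.score_thresh):
                    mask = probs[q] > self.config.mask_thresh
                    if mask.any():
                        detections.append((float(fg[q]), y0, x0, mask))
        # global greedy assembly: highest score claims its pixels first
        labels = np.zeros((H, W), dtype=np.int32)
        scores: list[float] = []
        nxt = 0
        for score, y0, x0, mask in sorted(detections, key=lambda d: -d[0]):
            region = labels[y0:y0 + mask.shape[0], x0:x0 + mask.shape[1]]
            free = mask & (region == 0)
            # mostly-covered duplicates from neighboring windows vanish
            if free.sum() < 0.25 * mask.sum():
                continue
            nxt += 1
            region[free] = nxt
            scores.append(score)
        from .core_io import relabel_contiguous
        labels = relabel_contiguous(labels)
        return Instances(InstanceLabelMap(labels), scores,
                         int(labels.max(initial=0)))

    def evaluate(self, pairs: list[tuple[ImageTile, InstanceLabelMap]]
                 ) -> MetricReport:
        report = MetricReport()
        for tile, gt in pairs:
            pred = self.predict(tile)
            report.add(tile.id, pred.label_map, gt)
        return report

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        self.network.save_checkpoint(path)

    @classmethod
    def load(cls, path: str | Path) -> "GlandSegmentationResults":
        net = SegmentationNetwork.load_checkpoint(path)
        return cls(None, net, [])

    # -- reporting -----------------------------------------------------
    def summary(self, eval_pairs=None) -> str:
        cfg = self.config
        losses = self.loss_trace
        lines = [
            "Gland instance segmentation — fit summary",
            "=" * 49,
            f"preset:            {'tiny' if cfg.tiny_preset else 'full'}",
            f"embed_dim:         {cfg.embed_dim}",
            f"decoder_dim:       {cfg.decoder_dim}",
            f"queries (N):       {cfg.n_queries}",
            f"decoder layers:    {cfg.n_decoder_layers} "
            f"(cycling 1/16 -> 1/8 -> 1/4, three rounds)",
            f"parameters:        {sum(p.data.size for p in self.network.parameters()):,}",
            f"iterations:        {len(losses)}",
        ]
        if len(losses):
            k = min(10, len(losses))
            lines += [
                f"loss first {k}:     {losses[:k].mean():.4f}",
                f"loss last {k}:      {losses[-k:].mean():.4f}",
            ]
        if np.isfinite(self.fit_seconds):
            lines.append(f"fit time:          {self.fit_seconds:.1f}s")
        if eval_pairs is not None:
            agg = self.evaluate(eval_pairs).aggregate()
            lines += [
                "-" * 49,
                f"object F1:         {agg['f1_object']:.4f}",
                f"object Dice:       {agg['dice_object']:.4f}",
                f"object Hausdorff:  {agg['hausdorff_object']:.2f} px",
                f"pixel F1:          {agg['f1_pixel']:.4f}",
            ]
        return "\n".join(lines)
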