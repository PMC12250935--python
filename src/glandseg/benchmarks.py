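"""Standard desk-scale experiments: overfit check and learning check.

Both experiments use the tiny preset and the synthetic gland generator
at its default conditions (96 px tiles, 2-6 glands per tile, radii
8-28 px, i.e. a 3.5x size span).  They are the package's own benchmark
protocol, shared by the test-suite and ``scripts/acceptance.py``:

* ``overfit_experiment`` — 8 fixed tiles, 300 iterations, no
  augmentation; reports the ratio of the final to the initial
  10-iteration mean loss.  A ratio well below 1 shows the full
  pipeline (matching, losses, gradients through every module) can
  memorize a small sample.
* ``learning_experiment`` — 64 training tiles with flip/rotation
  augmentation, evaluation on 16 held-out tiles; reports the
  object-level metrics.  This demonstrates the full
  train -> predict -> evaluate loop segments variant-size glands on
  unseen data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import RunConfig
from .model import GlandSegmentationModel, GlandSegmentationResults
from .synthetic import AugmentConfig, SynthSpec, augment, generate_dataset

__all__ = ["OverfitResult", "LearningResult", "overfit_experiment",
           "learning_experiment"]

LEARNING_ITERATIONS = 3500
OVERFIT_ITERATIONS = 300


@dataclass
class OverfitResult:
    first10_mean: float
    last10_mean: float
    results: GlandSegmentationResults

    @property
    def ratio(self) -> float:
        return self.last10_mean / self.first10_mean


@dataclass
class LearningResult:
    aggregate: dict
    loss_first10: float
    loss_last10: float
    results: GlandSegmentationResults
    n_eval: int


def overfit_experiment(seed: int = 0,
                       iterations: int = OVERFIT_ITERATIONS) -> OverfitResult:
    """Tiny preset, 8 fixed synthetic tiles, no augmentation."""
    cfg = RunConfig.tiny(seed=seed)
    spec = SynthSpec(tile_size=cfg.tile_size, seed=seed)
    model = GlandSegmentationModel(generate_dataset(spec, 8, seed=seed), cfg)
    res = model.fit(iterations=iterations, seed=seed, log_every=0)
    losses = res.loss_trace
    return OverfitResult(float(losses[:10].mean()),
                         float(losses[-10:].mean()), res)


def _geometric_augment(tile, imap, seed):
    # flips and 90-degree rotations only: color is the discriminative
    # cue in the synthetic tiles, so photometric jitter is left off here
    cfg = AugmentConfig(brightness=0, contrast=0, saturation=0, hue=0)
    return augment(tile, imap, seed, cfg)


def learning_experiment(seed: int = 0,
                        iterations: int = LEARNING_ITERATIONS,
                        n_train: int = 64, n_eval: int = 16
                        ) -> LearningResult:
    """Train on synthetic tiles, evaluate on held-out synthetic tiles."""
    cfg = RunConfig.tiny(seed=seed)
    spec = SynthSpec(tile_size=cfg.tile_size, seed=seed)
    train = generate_dataset(spec, n_train, seed=seed)
    held = generate_dataset(spec, n_eval, seed=seed + 1)
    model = GlandSegmentationModel(train, cfg, augment_fn=_geometric_augment)
    res = model.fit(iterations=iterations, seed=seed, log_every=0)
    report = res.evaluate(held)
    losses = res.loss_trace
    return LearningResult(report.aggregate(), float(losses[:10].mean()),
                          float(losses[-10:].mean()), res, n_eval)
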