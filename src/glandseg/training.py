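"""Bipartite matching, losses and the training loop.

Training follows the standard set-prediction recipe: each ground-truth
object is matched one-to-one with the query of minimal cost (Hungarian
assignment on a cost matrix combining class probability, binary
cross-entropy and soft Dice), matched queries are supervised toward
their object's mask and the foreground class, unmatched queries toward
the no-object class (down-weighted), and the loss is applied to every
decoder layer's predictions (deep supervision), including the layer-0
prediction from the initialized queries.

Ground-truth masks are compared at 1/4 scale — a nearest-neighbor
downsample of the instance map — to match the resolution of the
predicted mask logits.  Losses are computed on full mask grids rather
than sampled points: point sampling is a GPU-memory optimization with
no benefit at the sizes this package trains at.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._autodiff import Tensor, log, sigmoid
from .core_io import ImageTile, InstanceLabelMap, RunConfig
from .mask_decoder import QueryState
from .network import SegmentationNetwork
from .nn import AdamW

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "match_cost", "hungarian_match", "downsample_gt",
           "layer_loss", "total_loss", "Trainer", "train"]


@dataclass
class MatchResult:
    """One-to-one assignment of queries to ground-truth objects."""

    pairs: list[tuple[int, int]]        # (query index, gt index)
    unmatched_queries: list[int]        # assigned to no-object
    total_cost: float

    def __post_init__(self):
        gts = [j for _, j in self.pairs]
        if len(set(gts)) != len(gts):
            raise ValueError("a gt object was matched to two queries")


def downsample_gt(imap: InstanceLabelMap, stride: int = 4) -> np.ndarray:
    """(K, H/s, W/s) binary masks by nearest-neighbor (half-pixel
    centers: sample at row/col s*i + s//2)."""
    lab = imap.labels[stride // 2::stride, stride // 2::stride]
    K = imap.n_objects
    return np.stack([(lab == k).astype(np.float32)
                     for k in range(1, K + 1)]) if K else \
        np.zeros((0,) + lab.shape, dtype=np.float32)


def _sigmoid_np(x):
    from scipy.special import expit
    return expit(x)


def match_cost(mask_logits: np.ndarray, class_logits: np.ndarray,
               gt_masks: np.ndarray, gt_classes: np.ndarray,
               weights: tuple[float, float, float] = (2.0, 5.0, 5.0)
               ) -> np.ndarray:
    """N x K matching cost: lambda_cls * (-p(gt class)) + lambda_bce *
    mean BCE + lambda_dice * (1 - soft Dice).  Pure numpy (the matching
    is not differentiated through)."""
    lam_cls, lam_bce, lam_dice = weights
    N = mask_logits.shape[0]
    K = gt_masks.shape[0]
    if K == 0:
        return np.zeros((N, 0))
    cls = class_logits.astype(np.float64)
    e = np.exp(cls - cls.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    cost_cls = -probs[:, gt_classes]                       # (N, K)

    pm = mask_logits.reshape(N, -1).astype(np.float64)
    gm = gt_masks.reshape(K, -1).astype(np.float64)
    p = _sigmoid_np(pm)
    # mean BCE between every (query, object) pair, assembled from logits
    pos = np.logaddexp(0.0, -pm)                           # -log sigmoid
    neg = np.logaddexp(0.0, pm)                            # -log (1-sigmoid)
    n_pix = pm.shape[1]
    cost_bce = (pos @ gm.T + neg @ (1.0 - gm).T) / n_pix
    inter = p @ gm.T
    denom = p.sum(axis=1, keepdims=True) + gm.sum(axis=1)[None, :]
    cost_dice = 1.0 - (2.0 * inter + 1.0) / (denom + 1.0)
    return lam_cls * cost_cls + lam_bce * cost_bce + lam_dice * cost_dice


def hungarian_match(cost: np.ndarray) -> MatchResult:
    """Minimal-cost one-to-one assignment covering every gt object."""
    N, K = cost.shape
    if K > N:
        raise ValueError(f"{K} objects but only {N} queries; "
                         "increase n_queries in the config")
    if not np.isfinite(cost).all():
        raise ValueError("matching costs must be finite")
    if K == 0:
        return MatchResult([], list(range(N)), 0.0)
    qi, gj = linear_sum_assignment(cost)
    pairs = sorted(zip(qi.tolist(), gj.tolist()), key=lambda t: t[1])
    total = float(cost[qi, gj].sum())
    matched = {q for q, _ in pairs}
    return MatchResult(pairs, [q for q in range(N) if q not in matched], total)


def layer_loss(mask_logits: Tensor, class_logits: Tensor,
               gt_masks: np.ndarray, gt_classes: np.ndarray,
               match: MatchResult, config: RunConfig) -> Tensor:
    """Loss of one decoder layer under a given matching."""
    N = class_logits.shape[0]
    n_cls = class_logits.shape[1]

    # classification: cross-entropy with down-weighted no-object
    target = np.full(N, n_cls - 1, dtype=np.int64)
    for q, j in match.pairs:
        target[q] = int(gt_classes[j])
    w = np.where(target == n_cls - 1, config.no_object_weight, 1.0
                 ).astype(np.float32)
    logp = _log_softmax(class_logits)
    picked = logp[np.arange(N), target]
    ce = (Tensor(w) * picked * -1.0).sum() * (1.0 / max(w.sum(), 1e-8))
    loss = ce * config.loss_weight_cls

    if match.pairs:
        q_idx = np.array([q for q, _ in match.pairs])
        g_idx = np.array([j for _, j in match.pairs])
        pm = mask_logits[q_idx].reshape(len(q_idx), -1)
        gm = Tensor(gt_masks[g_idx].reshape(len(g_idx), -1))
        p = sigmoid(pm)
        eps = 1e-6
        bce = (gm * log(p + eps) + (1.0 - gm) * log(1.0 - p + eps)) * -1.0
        bce = bce.mean(axis=1).mean()
        inter = (p * gm).sum(axis=1)
        denom = p.sum(axis=1) + gm.data.sum(axis=1)
        dice = 1.0 - (2.0 * inter + 1.0) / (denom + 1.0)
        loss = loss + bce * config.loss_weight_bce \
                    + dice.mean() * config.loss_weight_dice
    return loss


def _log_softmax(x: Tensor) -> Tensor:
    from ._autodiff import exp as _exp
    m = np.max(x.data, axis=-1, keepdims=True)
    z = x - Tensor(m)
    return z - log(_exp(z).sum(axis=-1, keepdims=True))


def total_loss(state: QueryState, imap: InstanceLabelMap,
               config: RunConfig) -> tuple[Tensor, dict[str, float]]:
    """Deep-supervised loss: every layer matched and scored separately."""
    gt_masks = downsample_gt(imap)
    gt_classes = np.zeros(imap.n_objects, dtype=np.int64)  # single category
    loss = None
    comps = {}
    for l, (ml, cl) in enumerate(zip(state.mask_logits, state.class_logits)):
        cost = match_cost(ml.data, cl.data, gt_masks, gt_classes,
                          (config.loss_weight_cls, config.loss_weight_bce,
                           config.loss_weight_dice))
        match = hungarian_match(cost)
        ll = layer_loss(ml, cl, gt_masks, gt_classes, match, config)
        comps[f"layer{l}"] = float(ll.data)
        loss = ll if loss is None else loss + ll
    comps["total"] = float(loss.data)
    return loss, comps


@dataclass
class TrainRecord:
    iteration: int
    loss: float
    components: dict[str, float] = field(default_factory=dict)


class Trainer:
    """Seeded single-image-per-step training loop with CSV loss trace."""

    def __init__(self, net: SegmentationNetwork, config: RunConfig | None = None):
        self.net = net
        self.config = config or net.config
        cfg = self.config
        self.optimizer = AdamW(
            [(net.head_parameters(), 1.0),
             (net.backbone_parameters(), cfg.backbone_lr_scale)],
            lr=cfg.lr, weight_decay=cfg.weight_decay,
            clip_grad_norm=cfg.clip_grad_norm)
        self.trace: list[TrainRecord] = []

    def step(self, tile: ImageTile, imap: InstanceLabelMap) -> float:
        _, state = self.net.forward(tile.pixels)
        loss, comps = total_loss(state, imap, self.config)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged: loss={float(loss.data)} at "
                f"iteration {len(self.trace)}")
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.step()
        self.trace.append(TrainRecord(len(self.trace), float(loss.data), comps))
        return float(loss.data)

    def _lr_at(self, it: int, iterations: int) -> float:
        cfg = self.config
        lr = cfg.lr
        if cfg.lr_warmup_iters and it < cfg.lr_warmup_iters:
            lr *= (it + 1) / cfg.lr_warmup_iters
        if cfg.lr_decay_fraction and it >= cfg.lr_decay_fraction * iterations:
            lr *= cfg.lr_decay_factor
        return lr

    def fit(self, dataset, iterations: int, seed: int = 0,
            augment_fn=None, log_every: int = 50,
            callback=None) -> list[TrainRecord]:
        rng = np.random.default_rng(seed)
        t0 = time.time()
        for it in range(iterations):
            self.optimizer.lr = self._lr_at(it, iterations)
            tile, imap = dataset[int(rng.integers(len(dataset)))]
            if augment_fn is not None:
                tile, imap = augment_fn(tile, imap, int(rng.integers(2 ** 31)))
            loss = self.step(tile, imap)
            if log_every and (it + 1) % log_every == 0:
                logger.info("iter %d/%d loss=%.4f (%.1fs)",
                            it + 1, iterations, loss, time.time() - t0)
            if callback is not None:
                callback(it, loss)
        return self.trace

    def write_trace(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["iteration", "loss"])
            for r in self.trace:
                wr.writerow([r.iteration, f"{r.loss:.6f}"])


def train(config: RunConfig, dataset, iterations: int,
          checkpoint_path: str | Path | None = None,
          trace_path: str | Path | None = None,
          augment_fn=None) -> tuple[SegmentationNetwork, list[TrainRecord]]:
    """Build a fresh seeded network, train it, optionally save artifacts."""
    net = SegmentationNetwork(config)
    trainer = Trainer(net, config)
    trainer.fit(dataset, iterations, seed=config.seed, augment_fn=augment_fn)
    if trace_path is not None:
        trainer.write_trace(trace_path)
    if checkpoint_path is not None:
        net.save_checkpoint(checkpoint_path)
    return net, trainer.trace
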