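"""Object-level evaluation metrics for gland instance segmentation.

These are the gland-challenge conventions: detection F1 with the
50%-overlap rule, area-weighted object-level Dice, and area-weighted
object-level Hausdorff distance over boundary pixels, plus a plain
pixel-level F1.  Definitions:

* ``f1_object`` — a predicted object S_i counts as a true positive iff
  the ground-truth object it overlaps most satisfies
  |S_i ∩ G_j| > 0.5 |G_j| and has not already been claimed (claims are
  greedy in descending overlap, ties to the smaller label index).
* ``dice_object`` — D = 1/2 [ Σ_i γ_i Dice(S_i, G*(S_i))
  + Σ_j σ_j Dice(S*(G_j), G_j) ] with γ_i = |S_i| / Σ|S|,
  σ_j = |G_j| / Σ|G|; Dice against an empty best match is 0.
* ``hausdorff_object`` — same weighting with H(A, B) =
  max(max_a min_b ||a-b||, max_b min_a ||a-b||) over 8-connectivity
  boundary pixels; an object with no overlapping partner is paired with
  the *nearest* object of the other map (minimal boundary distance),
  and if the other map has no objects at all the image diagonal is used.
* ``f1_pixel`` — 2TP / (2TP + FP + FN) on binarized foreground.

Aggregates over a dataset are unweighted means of per-image values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion
from scipy.spatial.distance import cdist

from .core_io import InstanceLabelMap

__all__ = ["match_objects", "f1_object", "dice_object", "hausdorff_object",
           "f1_pixel", "evaluate_pair", "MetricReport", "boundary_pixels"]


def match_objects(S: InstanceLabelMap, G: InstanceLabelMap
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-overlap table and mutual best-match maps.

    Returns ``overlap`` of shape (nS+1, nG+1) (index 0 = background),
    ``g_star`` where g_star[i] is the gt label maximizing overlap with
    prediction i (0 if no overlap), and ``s_star`` symmetrically.
    Ties break toward the smaller label index.
    """
    if S.shape != G.shape:
        raise ValueError("label maps must share a shape")
    nS, nG = S.n_objects, G.n_objects
    overlap = np.zeros((nS + 1, nG + 1), dtype=np.int64)
    np.add.at(overlap, (S.labels.ravel(), G.labels.ravel()), 1)
    g_star = np.zeros(nS + 1, dtype=np.int64)
    s_star = np.zeros(nG + 1, dtype=np.int64)
    for i in range(1, nS + 1):
        row = overlap[i, 1:]
        if nG and row.max() > 0:
            g_star[i] = int(row.argmax()) + 1  # argmax takes first = smaller
    for j in range(1, nG + 1):
        col = overlap[1:, j]
        if nS and col.max() > 0:
            s_star[j] = int(col.argmax()) + 1
    return overlap, g_star, s_star


def f1_object(S: InstanceLabelMap, G: InstanceLabelMap) -> dict[str, float]:
    """Detection F1 under the 50%-of-ground-truth overlap rule."""
    overlap, g_star, _ = match_objects(S, G)
    nS, nG = S.n_objects, G.n_objects
    g_area = overlap[:, 1:].sum(axis=0)  # |G_j| for j=1..nG

    cands = []
    for i in range(1, nS + 1):
        j = g_star[i]
        if j > 0:
            cands.append((int(overlap[i, j]), i, int(j)))
    # greedy claiming in descending overlap; smaller label on ties
    cands.sort(key=lambda t: (-t[0], t[1]))
    claimed: set[int] = set()
    tp = 0
    for ov, i, j in cands:
        if j in claimed:
            continue
        if ov > 0.5 * g_area[j - 1]:
            claimed.add(j)
            tp += 1
    fp = nS - tp
    fn = nG - tp
    precision = tp / nS if nS else 0.0
    recall = tp / nG if nG else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn}


def _dice(a_area: int, b_area: int, inter: int) -> float:
    if a_area + b_area == 0:
        return 0.0
    return 2.0 * inter / (a_area + b_area)


def dice_object(S: InstanceLabelMap, G: InstanceLabelMap) -> float:
    """Area-weighted symmetrized object-level Dice."""
    overlap, g_star, s_star = match_objects(S, G)
    nS, nG = S.n_objects, G.n_objects
    s_area = overlap[1:, :].sum(axis=1)
    g_area = overlap[:, 1:].sum(axis=0)
    total_s, total_g = s_area.sum(), g_area.sum()

    term_s = 0.0
    for i in range(1, nS + 1):
        j = g_star[i]
        d = _dice(s_area[i - 1], g_area[j - 1], overlap[i, j]) if j else 0.0
        term_s += (s_area[i - 1] / total_s) * d if total_s else 0.0
    term_g = 0.0
    for j in range(1, nG + 1):
        i = s_star[j]
        d = _dice(s_area[i - 1], g_area[j - 1], overlap[i, j]) if i else 0.0
        term_g += (g_area[j - 1] / total_g) * d if total_g else 0.0
    return 0.5 * (term_s + term_g)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of the 8-connectivity boundary: object pixels
    with at least one non-object pixel among their 8 neighbors (or on
    the image border)."""
    er = binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return np.argwhere(mask & ~er)


def _hausdorff(pa: np.ndarray, pb: np.ndarray) -> float:
    d = cdist(pa.astype(np.float64), pb.astype(np.float64))
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def hausdorff_object(S: InstanceLabelMap, G: InstanceLabelMap) -> float:
    """Area-weighted symmetrized object-level Hausdorff distance."""
    overlap, g_star, s_star = match_objects(S, G)
    nS, nG = S.n_objects, G.n_objects
    s_area = overlap[1:, :].sum(axis=1)
    g_area = overlap[:, 1:].sum(axis=0)
    total_s, total_g = s_area.sum(), g_area.sum()
    diag = float(np.hypot(*S.shape))

    s_bnd = [boundary_pixels(S.labels == i) for i in range(1, nS + 1)]
    g_bnd = [boundary_pixels(G.labels == j) for j in range(1, nG + 1)]

    def nearest(bnd, others):
        """index of the other-map object with minimal boundary distance"""
        best, best_d = 0, np.inf
        for idx, ob in enumerate(others, start=1):
            d = cdist(bnd, ob).min()
            if d < best_d:
                best_d, best = d, idx
        return best

    def h_for(bnd, partner_label, others):
        if partner_label == 0:
            if not others:
                return diag
            partner_label = nearest(bnd, others)
        return _hausdorff(bnd, others[partner_label - 1])

    term_s = 0.0
    for i in range(1, nS + 1):
        h = h_for(s_bnd[i - 1], int(g_star[i]), g_bnd)
        term_s += (s_area[i - 1] / total_s) * h if total_s else 0.0
    term_g = 0.0
    for j in range(1, nG + 1):
        h = h_for(g_bnd[j - 1], int(s_star[j]), s_bnd)
        term_g += (g_area[j - 1] / total_g) * h if total_g else 0.0
    return 0.5 * (term_s + term_g)


def f1_pixel(S: InstanceLabelMap, G: InstanceLabelMap) -> float:
    """Pixel-level F1 on binarized foreground (1.0 if both are empty)."""
    s = S.labels > 0
    g = G.labels > 0
    tp = int((s & g).sum())
    fp = int((s & ~g).sum())
    fn = int((~s & g).sum())
    if tp + fp + fn == 0:
        return 1.0
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class MetricReport:
    """Per-image rows and aggregate (unweighted mean) metrics."""

    per_image: list[dict] = field(default_factory=list)

    def add(self, image_id: str, S: InstanceLabelMap, G: InstanceLabelMap
            ) -> dict:
        det = f1_object(S, G)
        row = {
            "image_id": image_id,
            "f1_object": det["f1"],
            "precision": det["precision"],
            "recall": det["recall"],
            "tp": det["tp"], "fp": det["fp"], "fn": det["fn"],
            "dice_object": dice_object(S, G),
            "hausdorff_object": hausdorff_object(S, G),
            "f1_pixel": f1_pixel(S, G),
            "n_pred": S.n_objects, "n_gt": G.n_objects,
        }
        self.per_image.append(row)
        return row

    def aggregate(self) -> dict[str, float]:
        if not self.per_image:
            return {}
        keys = ("f1_object", "dice_object", "hausdorff_object", "f1_pixel")
        agg = {k: float(np.mean([r[k] for r in self.per_image])) for k in keys}
        agg["n_images"] = len(self.per_image)
        return agg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"per_image": self.per_image,
                       "aggregate": self.aggregate()}, fh, indent=2)

    def to_csv(self, path) -> None:
        import csv
        if not self.per_image:
            return
        with open(path, "w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=list(self.per_image[0]))
            wr.writeheader()
            wr.writerows(self.per_image)


def evaluate_pair(S: InstanceLabelMap, G: InstanceLabelMap) -> dict:
    """All four metrics for one prediction/ground-truth pair."""
    rep = MetricReport()
    return rep.add("", S, G)
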