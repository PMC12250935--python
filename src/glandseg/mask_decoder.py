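"""Masked-attention transformer decoder and instance assembly.

N learned queries attend to the integrated feature maps g16, g8, g4 in
that order, cycling through the three scales three times (nine layers).
The cross-attention of layer l is masked: logits at positions outside
the *previous* layer's predicted object mask are set to -inf, so each
query focuses on its own object region,

    X_l = softmax(M_{l-1} + Q_l K_l^T) V_l + X_{l-1},

with Q from the query state and K, V from the scale's feature map.  A
query whose mask row is entirely -inf would produce NaNs; its row falls
back to all zeros (attend everywhere) — that fallback is mandatory.
Each layer additionally runs self-attention over the queries and a
feed-forward sublayer (pre-norm).  Mask predictions exist for every
layer, including layer 0 (from the initialized queries): the query
state is sent through a small MLP and dotted with p4 per pixel.  The
final instance map is assembled from the layer-9 masks and an MLP class
head, resolving pixel conflicts by query score.

X0 is a learnable N x C parameter initialized to zeros.  Sinusoidal
positional encodings are added to K and a learned query embedding to Q
(switchable off).  Attention masks are recomputed from detached mask
logits — gradients flow through the attention softmax, not through the
mask binarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, matmul, reshape, softmax, transpose
from .core_io import InstanceLabelMap, RunConfig, relabel_contiguous
from .encoder import FeaturePyramid
from .nn import (LayerNorm, Linear, Mlp, Module, Parameter, resize_map_np,
                 sinusoidal_position_encoding, trunc_normal)

__all__ = ["QueryState", "MaskedAttention", "DecoderLayer", "MaskDecoder",
           "make_attention_mask", "postprocess", "Instances"]

NEG_INF = -np.inf


@dataclass
class QueryState:
    """Per-layer decoder state and predictions.

    ``queries[l]`` is X_l (N x C); ``mask_logits[l]`` are the N mask
    logit maps at 1/4 scale predicted from X_l (l = 0 .. n_layers);
    ``class_logits[l]`` the N x (n_classes+1) class logits.
    """

    queries: list[Tensor] = field(default_factory=list)
    mask_logits: list[Tensor] = field(default_factory=list)
    class_logits: list[Tensor] = field(default_factory=list)
    scales_used: list[int] = field(default_factory=list)

    @property
    def final_masks(self) -> Tensor:
        return self.mask_logits[-1]

    @property
    def final_classes(self) -> Tensor:
        return self.class_logits[-1]


class MaskedAttention(Module):
    """Multi-head cross-attention with an additive {0, -inf} mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must divide into heads")
        self.dim, self.n_heads = dim, n_heads
        self.f_q = Linear(dim, dim, rng)
        self.f_k = Linear(dim, dim, rng)
        self.f_v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, kv: Tensor, attn_mask: np.ndarray | None,
                 q_pos: Tensor | None = None,
                 k_pos: np.ndarray | None = None) -> Tensor:
        """x: (N, C) queries; kv: (S, C) flattened feature tokens;
        attn_mask: constant (N, S) array with entries in {0, -inf}."""
        N, C = x.shape
        S = kv.shape[0]
        h, dh = self.n_heads, C // self.n_heads
        q_in = x if q_pos is None else x + q_pos
        k_in = kv if k_pos is None else kv + Tensor(k_pos)
        q = self.f_q(q_in).reshape(N, h, dh) * np.float32(dh ** -0.5)
        k = self.f_k(k_in).reshape(S, h, dh)
        v = self.f_v(kv).reshape(S, h, dh)
        qh = transpose(q, (1, 0, 2))                 # (h, N, dh)
        kh = transpose(k, (1, 2, 0))                 # (h, dh, S)
        logits = matmul(qh, kh)                      # (h, N, S)
        if attn_mask is not None:
            logits = logits + Tensor(attn_mask[None, :, :])
        attn = softmax(logits, axis=2)
        vh = transpose(v, (1, 0, 2))                 # (h, S, dh)
        out = matmul(attn, vh)                       # (h, N, dh)
        out = transpose(out, (1, 0, 2)).reshape(N, C)
        return self.proj(out)


class DecoderLayer(Module):
    """Masked cross-attention -> query self-attention -> feed-forward."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.cross = MaskedAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.self_attn = MaskedAttention(dim, n_heads, rng)
        self.norm3 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor, kv: Tensor, attn_mask, q_pos, k_pos) -> Tensor:
        x = self.cross(self.norm1(x), kv, attn_mask, q_pos, k_pos) + x
        xs = self.norm2(x)
        x = self.self_attn(xs, xs, None, q_pos,
                           q_pos.data if q_pos is not None else None) + x
        x = x + self.mlp(self.norm3(x))
        return x


def make_attention_mask(mask_logits: np.ndarray, h_out: int, w_out: int
                        ) -> np.ndarray:
    """Binarize sigmoid(mask logits) at 0.5 after bilinear resize.

    mask_logits: (N, H, W) *detached* array.  Returns (N, h_out*w_out)
    with entries 0 (attend) where the resized probability >= 0.5 and
    -inf elsewhere.  Rows that end up all -inf are replaced by all-zero
    rows so their queries attend everywhere instead of producing NaNs.
    """
    from scipy.special import expit
    probs = expit(mask_logits.astype(np.float32))
    small = resize_map_np(probs, h_out, w_out, "bilinear")
    keep = small >= 0.5
    M = np.where(keep, 0.0, NEG_INF).astype(np.float32)
    dead = ~keep.reshape(keep.shape[0], -1).any(axis=1)
    M[dead] = 0.0
    return M.reshape(mask_logits.shape[0], h_out * w_out)


class MaskHead(Module):
    """3-layer perceptron C -> C producing per-query mask embeddings."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, dim, rng)
        self.fc2 = Linear(dim, dim, rng)
        self.fc3 = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        from ._autodiff import relu
        return self.fc3(relu(self.fc2(relu(self.fc1(x)))))


class MaskDecoder(Module):
    """Nine decoder layers cycling g16 -> g8 -> g4 three times."""

    SCALE_ORDER = (16, 8, 4)

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        D = config.decoder_dim
        self.config = config
        self.n_layers = config.n_decoder_layers
        # learnable input query feature, zero-initialized
        self.x0 = Parameter(np.zeros((config.n_queries, D), dtype=np.float32))
        self.query_embed = Parameter(
            trunc_normal(rng, (config.n_queries, D), 0.02))
        self.layers = [DecoderLayer(D, config.n_decoder_heads,
                                    config.mlp_ratio, rng)
                       for _ in range(self.n_layers)]
        self.decoder_norm = LayerNorm(D)
        self.mask_head = MaskHead(D, rng)
        self.class_head = Mlp(D, D, rng, n_out=config.n_classes + 1)

    # -- prediction heads --------------------------------------------
    def predict_masks(self, x: Tensor, p4: Tensor) -> Tensor:
        """mask_logits[n, y, x] = < mask_head(X)[n], p4[:, y, x] >."""
        C, H4, W4 = p4.shape
        emb = self.mask_head(self.decoder_norm(x))          # (N, C)
        flat = p4.reshape(C, H4 * W4)
        return matmul(emb, flat).reshape(x.shape[0], H4, W4)

    def predict_classes(self, x: Tensor) -> Tensor:
        return self.class_head(self.decoder_norm(x))

    # -- full decode ---------------------------------------------------
    def __call__(self, pyr: FeaturePyramid) -> QueryState:
        cfg = self.config
        gmaps = {16: pyr.g16, 8: pyr.g8, 4: pyr.g4}
        p4 = pyr.p4
        state = QueryState()
        x = self.x0 * 1.0  # graph node so x0 receives gradient
        q_pos = self.query_embed if cfg.use_positional_encoding else None

        state.queries.append(x)
        state.mask_logits.append(self.predict_masks(x, p4))
        state.class_logits.append(self.predict_classes(x))

        for l in range(1, self.n_layers + 1):
            scale = self.SCALE_ORDER[(l - 1) % 3]
            g = gmaps[scale]
            C, H, W = g.shape
            kv = transpose(g, (1, 2, 0)).reshape(H * W, C)
            k_pos = (sinusoidal_position_encoding(H, W, C)
                     if cfg.use_positional_encoding else None)
            attn_mask = make_attention_mask(
                state.mask_logits[-1].data, H, W)
            x = self.layers[l - 1](x, kv, attn_mask, q_pos, k_pos)
            state.queries.append(x)
            state.mask_logits.append(self.predict_masks(x, p4))
            state.class_logits.append(self.predict_classes(x))
            state.scales_used.append(scale)
        return state


# -- instance assembly ------------------------------------------------

@dataclass
class Instances:
    """Final per-image instance predictions."""

    label_map: InstanceLabelMap
    scores: list[float]
    count: int


def postprocess(mask_logits: np.ndarray, class_logits: np.ndarray,
                out_h: int, out_w: int, score_thresh: float = 0.5,
                mask_thresh: float = 0.5) -> Instances:
    """Assemble an instance label map from the final query predictions.

    Queries whose foreground probability exceeds ``score_thresh`` are
    kept; their mask logits are bilinearly upsampled to (out_h, out_w)
    and binarized at ``mask_thresh``.  A pixel claimed by several
    queries goes to the highest-scoring one; empty instances are
    dropped and labels are contiguous in descending score order.
    """
    if not (0.0 < score_thresh < 1.0 and 0.0 < mask_thresh < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    cls = np.asarray(class_logits, dtype=np.float64)
    e = np.exp(cls - cls.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    fg_score = 1.0 - probs[:, -1]  # total foreground probability
    keep = np.flatnonzero(fg_score > score_thresh)
    H, W = out_h, out_w
    labels = np.zeros((H, W), dtype=np.int32)
    if keep.size == 0:
        return Instances(InstanceLabelMap(labels, 0), [], 0)

    order = keep[np.argsort(-fg_score[keep], kind="stable")]
    best_score = np.full((H, W), -1.0)
    winner = np.zeros((H, W), dtype=np.int64)  # 1-based into `order`
    for rank, qi in enumerate(order, start=1):
        from scipy.special import expit
        up = resize_map_np(np.asarray(mask_logits[qi], dtype=np.float32),
                           H, W, "bilinear")
        prob = expit(up)
        m = prob > mask_thresh
        take = m & (fg_score[qi] > best_score)
        winner[take] = rank
        best_score[take] = fg_score[qi]

    scores = []
    nxt = 0
    for rank, qi in enumerate(order, start=1):
        pix = winner == rank
        if pix.any():
            nxt += 1
            labels[pix] = nxt
            scores.append(float(fg_score[qi]))
    return Instances(InstanceLabelMap(labels, nxt), scores, nxt)
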