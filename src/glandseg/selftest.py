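"""Built-in oracle self-test: every attention/matching/metric primitive
is recomputed by a deliberately naive per-element loop and compared.

Runs in seconds on one CPU.  ``run_selftest`` returns a list of
(name, passed, detail) rows; the CLI prints them as a table.  A
``corrupt_metrics`` flag substitutes a broken Dice on purpose — a
mutation control demonstrating that the harness actually detects
failures.
"""

from __future__ import annotations

import itertools
import time

import numpy as np

from ._autodiff import Tensor
from .core_io import InstanceLabelMap, RunConfig
from .csgi import GuidanceBlock, upsample_bicubic
from .encoder import NeighborhoodAttention, na_indices
from .mask_decoder import MaskedAttention
from .metrics import dice_object, f1_object, hausdorff_object
from .pixel_decoder import MSDeformAttention
from .training import hungarian_match

__all__ = ["run_selftest", "format_report"]


# -- naive oracles ----------------------------------------------------

def na_oracle(module: NeighborhoodAttention, x: np.ndarray, H: int, W: int
              ) -> np.ndarray:
    """Per-pixel loop re-implementation of neighborhood attention."""
    h, dh = module.n_heads, module.dim // module.n_heads
    Wqkv, bqkv = module.qkv.weight.data, module.qkv.bias.data
    qkv = x @ Wqkv + bqkv
    q, k, v = (qkv[:, i * module.dim:(i + 1) * module.dim] for i in range(3))
    idx = na_indices(H, W, module.kernel, module.dilation)
    out = np.zeros_like(x)
    for pos in range(H * W):
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            qv = q[pos, sl] / np.sqrt(dh)
            logits = []
            for slot, nb in enumerate(idx[pos]):
                logits.append(qv @ k[nb, sl] + module.rel_bias.data[head, slot])
            logits = np.array(logits)
            w = np.exp(logits - logits.max())
            w /= w.sum()
            acc = np.zeros(dh)
            for slot, nb in enumerate(idx[pos]):
                acc += w[slot] * v[nb, sl]
            out[pos, sl] = acc
    return out @ module.proj.weight.data + module.proj.bias.data


def deform_oracle(module: MSDeformAttention, query: np.ndarray,
                  values: list[np.ndarray], shapes, ref: np.ndarray
                  ) -> np.ndarray:
    """Per-query loop with explicit bilinear interpolation."""
    S = query.shape[0]
    h, P, L, D = (module.n_heads, module.n_points, module.n_levels,
                  module.dim)
    dh = D // h
    off = (query @ module.offset_proj.weight.data
           + module.offset_proj.bias.data).reshape(S, h, L, P, 2)
    aw = (query @ module.weight_proj.weight.data
          + module.weight_proj.bias.data).reshape(S, h, L * P)
    aw = np.exp(aw - aw.max(axis=2, keepdims=True))
    aw /= aw.sum(axis=2, keepdims=True)
    aw = aw.reshape(S, h, L, P)
    vproj = [v @ module.value_proj.weight.data + module.value_proj.bias.data
             for v in values]
    out = np.zeros((S, D))
    for s in range(S):
        for head in range(h):
            acc = np.zeros(dh)
            for lvl, (H, W) in enumerate(shapes):
                v = vproj[lvl].reshape(H, W, h, dh)
                for p in range(P):
                    lx = ref[s, 0] + off[s, head, lvl, p, 0] / W
                    ly = ref[s, 1] + off[s, head, lvl, p, 1] / H
                    lx, ly = np.clip(lx, 0, 1), np.clip(ly, 0, 1)
                    px = np.clip(lx * W - 0.5, 0, W - 1)
                    py = np.clip(ly * H - 0.5, 0, H - 1)
                    x0 = min(int(np.floor(px)), max(W - 2, 0))
                    y0 = min(int(np.floor(py)), max(H - 2, 0))
                    x1, y1 = min(x0 + 1, W - 1), min(y0 + 1, H - 1)
                    fx, fy = np.clip(px - x0, 0, 1), np.clip(py - y0, 0, 1)
                    val = ((1 - fy) * (1 - fx) * v[y0, x0, head]
                           + (1 - fy) * fx * v[y0, x1, head]
                           + fy * (1 - fx) * v[y1, x0, head]
                           + fy * fx * v[y1, x1, head])
                    acc += aw[s, head, lvl, p] * val
            out[s, head * dh:(head + 1) * dh] = acc
    return out @ module.output_proj.weight.data + module.output_proj.bias.data


def masked_attention_oracle(module: MaskedAttention, x: np.ndarray,
                            kv: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Brute-force masked cross-attention (no positional terms)."""
    N, C = x.shape
    S = kv.shape[0]
    h, dh = module.n_heads, C // module.n_heads
    q = x @ module.f_q.weight.data + module.f_q.bias.data
    k = kv @ module.f_k.weight.data + module.f_k.bias.data
    v = kv @ module.f_v.weight.data + module.f_v.bias.data
    out = np.zeros((N, C))
    for n in range(N):
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            logits = np.array([q[n, sl] @ k[s, sl] / np.sqrt(dh) + M[n, s]
                               for s in range(S)])
            w = np.exp(logits - logits[np.isfinite(logits)].max())
            w[~np.isfinite(logits)] = 0.0
            w /= w.sum()
            out[n, sl] = sum(w[s] * v[s, sl] for s in range(S))
    return out @ module.proj.weight.data + module.proj.bias.data


def hungarian_oracle(cost: np.ndarray) -> float:
    """Exhaustive search over all one-to-one assignments."""
    N, K = cost.shape
    best = np.inf
    for perm in itertools.permutations(range(N), K):
        best = min(best, sum(cost[q, j] for j, q in enumerate(perm)))
    return best


# -- suites -----------------------------------------------------------

def _suite_neighborhood(rng) -> tuple[bool, str]:
    worst = 0.0
    for H, W in ((6, 6), (5, 8), (8, 8)):
        for k, d in ((1, 1), (3, 1), (3, 2)):
            mod = NeighborhoodAttention(8, 2, k, d, rng)
            x = rng.standard_normal((H * W, 8)).astype(np.float32)
            got = mod(Tensor(x), H, W).data
            want = na_oracle(mod, x, H, W)
            worst = max(worst, float(np.abs(got - want).max()))
    return worst <= 1e-5, f"max|Δ|={worst:.2e}"


def _suite_deformable(rng) -> tuple[bool, str]:
    shapes = [(8, 8), (4, 4), (2, 2)]
    mod = MSDeformAttention(8, 2, 2, 3, rng)
    mod.offset_proj.weight.data = 0.1 * rng.standard_normal(
        mod.offset_proj.weight.data.shape).astype(np.float32)
    mod.weight_proj.weight.data = 0.1 * rng.standard_normal(
        mod.weight_proj.weight.data.shape).astype(np.float32)
    values = [rng.standard_normal((H * W, 8)).astype(np.float32)
              for H, W in shapes]
    refs = []
    for H, W in shapes:
        ys, xs = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        refs.append(np.stack([(xs.ravel() + .5) / W, (ys.ravel() + .5) / H], 1))
    ref = np.concatenate(refs)
    q = np.concatenate(values)
    got = mod(Tensor(q), [Tensor(v) for v in values], shapes, ref).data
    want = deform_oracle(mod, q, values, shapes, ref)
    err = float(np.abs(got - want).max())
    return err <= 1e-5, f"max|Δ|={err:.2e}"


def _suite_masked_attention(rng) -> tuple[bool, str]:
    worst = 0.0
    for trial in range(5):
        mod = MaskedAttention(8, 2, rng)
        x = rng.standard_normal((2, 8)).astype(np.float32)
        kv = rng.standard_normal((3, 8)).astype(np.float32)
        M = np.where(rng.random((2, 3)) < 0.4, -np.inf, 0.0).astype(np.float32)
        M[~np.isfinite(M).any(axis=1) | (M == 0).any(axis=1), :] # noqa
        for n in range(2):  # guarantee a finite entry per row
            if not np.isfinite(M[n]).any() or not (M[n] == 0).any():
                M[n, 0] = 0.0
        got = mod(Tensor(x), Tensor(kv), M).data
        want = masked_attention_oracle(mod, x, kv, M)
        worst = max(worst, float(np.abs(got - want).max()))
    return worst <= 1e-5, f"max|Δ|={worst:.2e}"


def _suite_hungarian(rng) -> tuple[bool, str]:
    for trial in range(20):
        N = int(rng.integers(2, 7))
        K = int(rng.integers(1, min(N, 4) + 1))
        cost = rng.random((N, K))
        res = hungarian_match(cost)
        want = hungarian_oracle(cost)
        if abs(res.total_cost - want) > 1e-9:
            return False, f"trial {trial}: {res.total_cost} vs {want}"
    return True, "20 random instances vs exhaustive search"


def _suite_csgi(rng) -> tuple[bool, str]:
    D = 8
    gb = GuidanceBlock(D, rng)
    p32 = Tensor(rng.standard_normal((D, 2, 2)).astype(np.float32))
    msgs = []
    ok = True
    for j, size in ((2, 4), (4, 8), (8, 16)):
        pk = Tensor(rng.standard_normal((D, size, size)).astype(np.float32))
        vk = gb(p32, pk, j)
        if vk.shape != (D, size, size):
            ok = False
            msgs.append(f"v at j={j} has shape {vk.shape}")
    v16 = rng.standard_normal((D, 4, 4)).astype(np.float32)
    v8 = rng.standard_normal((D, 8, 8)).astype(np.float32)
    up = upsample_bicubic(Tensor(v16), 2).data
    got = up * v8 + v8
    zero_case = np.abs((np.zeros_like(up) * v8 + v8) - v8).max()
    ones_case = np.abs((np.ones_like(up) * v8 + v8) - 2 * v8).max()
    if zero_case > 0 or ones_case > 0:
        ok = False
        msgs.append("identity cases failed")
    const = upsample_bicubic(Tensor(np.full((D, 3, 3), 2.5, np.float32)), 4).data
    if np.abs(const - 2.5).max() > 1e-5:
        ok = False
        msgs.append("bicubic does not reproduce constants")
    return ok, "; ".join(msgs) if msgs else "Eq. identities + shapes hold"


def _suite_metrics(corrupt: bool = False) -> tuple[bool, str]:
    dice_fn = dice_object if not corrupt else (
        lambda S, G: 0.5 * dice_object(S, G))  # mutation control
    lab = np.zeros((8, 8), np.int32)
    lab[1:5, 1:5] = 1
    G = InstanceLabelMap(lab)
    half = np.zeros((8, 8), np.int32)
    half[1:5, 1:3] = 1
    S = InstanceLabelMap(half)
    checks = [
        abs(dice_fn(G, G) - 1.0) < 1e-12,
        abs(dice_fn(S, G) - 2.0 / 3.0) < 1e-12,
        abs(f1_object(G, G)["f1"] - 1.0) < 1e-12,
        abs(hausdorff_object(G, G)) < 1e-12,
    ]
    a = np.zeros((6, 6), np.int32); a[0, 0] = 1
    b = np.zeros((6, 6), np.int32); b[3, 4] = 1
    checks.append(abs(hausdorff_object(InstanceLabelMap(a),
                                       InstanceLabelMap(b)) - 5.0) < 1e-12)
    ok = all(checks)
    return ok, f"{sum(checks)}/{len(checks)} toy identities"


def run_selftest(seed: int = 0, corrupt_metrics: bool = False
                 ) -> list[tuple[str, bool, str, float]]:
    """Run all oracle suites; returns (name, passed, detail, seconds)."""
    rng = np.random.default_rng(seed)
    suites = [
        ("neighborhood_attention", lambda: _suite_neighborhood(rng)),
        ("deformable_sampling", lambda: _suite_deformable(rng)),
        ("masked_attention", lambda: _suite_masked_attention(rng)),
        ("hungarian_matching", lambda: _suite_hungarian(rng)),
        ("cross_scale_equations", lambda: _suite_csgi(rng)),
        ("object_metrics", lambda: _suite_metrics(corrupt_metrics)),
    ]
    rows = []
    for name, fn in suites:
        t0 = time.time()
        try:
            ok, detail = fn()
        except Exception as exc:  # a crash is a failure, not an abort
            ok, detail = False, f"raised {type(exc).__name__}: {exc}"
        rows.append((name, ok, detail, time.time() - t0))
    return rows


def format_report(rows) -> str:
    width = max(len(r[0]) for r in rows)
    lines = [f"{'suite'.ljust(width)}  status  time    detail",
             "-" * (width + 40)]
    for name, ok, detail, dt in rows:
        lines.append(f"{name.ljust(width)}  {'PASS' if ok else 'FAIL'}  "
                     f"{dt:6.2f}s  {detail}")
    n_ok = sum(1 for r in rows if r[1])
    lines.append(f"{n_ok}/{len(rows)} suites passed")
    return "\n".join(lines)
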