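"""Masked attention vs brute force, mask prediction by inner products,
attention-mask construction with the all-masked fallback, the 9-layer
scale cycle, and instance assembly."""

import numpy as np
import pytest

from glandseg._autodiff import Tensor
from glandseg.core_io import RunConfig
from glandseg.encoder import FeaturePyramid
from glandseg.mask_decoder import (MaskDecoder, MaskedAttention,
                                   make_attention_mask, postprocess)


def masked_attn_loop_oracle(mod, x, kv, M):
    """Brute-force per-query softmax attention with -inf masking."""
    N, C = x.shape
    S = kv.shape[0]
    h, dh = mod.n_heads, C // mod.n_heads
    q = x @ mod.f_q.weight.data + mod.f_q.bias.data
    k = kv @ mod.f_k.weight.data + mod.f_k.bias.data
    v = kv @ mod.f_v.weight.data + mod.f_v.bias.data
    out = np.zeros((N, C))
    for n in range(N):
        for head in range(h):
            sl = slice(head * dh, (head + 1) * dh)
            logits = np.array([q[n, sl] @ k[s, sl] / np.sqrt(dh) + M[n, s]
                               for s in range(S)])
            finite = np.isfinite(logits)
            w = np.zeros(S)
            w[finite] = np.exp(logits[finite] - logits[finite].max())
            w /= w.sum()
            out[n, sl] = sum(w[s] * v[s, sl] for s in range(S))
    return out @ mod.proj.weight.data + mod.proj.bias.data


class TestMaskedAttention:
    def test_single_position_zero_mask_returns_value(self, rng):
        """softmax over one element is 1, so output = proj(V)."""
        mod = MaskedAttention(8, 2, rng)
        mod.proj.weight.data = np.eye(8, dtype=np.float32)
        mod.proj.bias.data[:] = 0.0
        x = rng.standard_normal((3, 8)).astype(np.float32)
        kv = rng.standard_normal((1, 8)).astype(np.float32)
        out = mod(Tensor(x), Tensor(kv), np.zeros((3, 1), np.float32)).data
        v = kv @ mod.f_v.weight.data + mod.f_v.bias.data
        np.testing.assert_allclose(out, np.tile(v, (3, 1)), atol=1e-5)

    def test_neg_inf_equals_deleting_the_position(self, rng):
        mod = MaskedAttention(8, 2, rng)
        x = rng.standard_normal((2, 8)).astype(np.float32)
        kv = rng.standard_normal((4, 8)).astype(np.float32)
        M = np.zeros((2, 4), np.float32)
        M[:, 2] = -np.inf
        with_mask = mod(Tensor(x), Tensor(kv), M).data
        deleted = mod(Tensor(x), Tensor(np.delete(kv, 2, axis=0)),
                      np.zeros((2, 3), np.float32)).data
        np.testing.assert_allclose(with_mask, deleted, atol=1e-5)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_oracle(self, trial, rng):
        mod = MaskedAttention(8, 2, rng)
        x = rng.standard_normal((2, 8)).astype(np.float32)
        kv = rng.standard_normal((3, 8)).astype(np.float32)
        M = np.where(rng.random((2, 3)) < 0.4, -np.inf, 0.0).astype(np.float32)
        M[:, 0] = 0.0  # keep every row alive
        got = mod(Tensor(x), Tensor(kv), M).data
        np.testing.assert_allclose(got, masked_attn_loop_oracle(mod, x, kv, M),
                                   atol=1e-5)

    def test_zero_mask_equals_plain_cross_attention(self, rng):
        mod = MaskedAttention(8, 2, rng)
        x = rng.standard_normal((4, 8)).astype(np.float32)
        kv = rng.standard_normal((6, 8)).astype(np.float32)
        a = mod(Tensor(x), Tensor(kv), np.zeros((4, 6), np.float32)).data
        b = mod(Tensor(x), Tensor(kv), None).data
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestAttentionMask:
    def test_confident_positive_logits_attend_everywhere(self):
        M = make_attention_mask(np.full((2, 8, 8), 10.0, np.float32), 4, 4)
        assert (M == 0).all()

    def test_confident_negative_logits_trigger_fallback(self):
        M = make_attention_mask(np.full((2, 8, 8), -10.0, np.float32), 4, 4)
        assert (M == 0).all()  # all--inf rows replaced by all-zero

    def test_half_plane_survives_resizing(self):
        logits = np.full((1, 16, 16), -10.0, np.float32)
        logits[0, :, :8] = 10.0
        M = make_attention_mask(logits, 4, 4).reshape(4, 4)
        assert (M[:, :2] == 0).all()
        assert np.isneginf(M[:, 2:]).all()

    def test_entries_are_only_zero_or_neg_inf(self, rng):
        M = make_attention_mask(
            rng.standard_normal((3, 8, 8)).astype(np.float32), 2, 2)
        assert np.all((M == 0) | np.isneginf(M))


class TestDecode:
    @pytest.fixture(scope="class")
    def decoded(self):
        cfg = RunConfig.tiny(n_queries=20, decoder_dim=64)
        rng = np.random.default_rng(0)
        dec = MaskDecoder(cfg, rng)
        pyr = FeaturePyramid(
            g16=Tensor(rng.standard_normal((64, 8, 8)).astype(np.float32)),
            g8=Tensor(rng.standard_normal((64, 16, 16)).astype(np.float32)),
            g4=Tensor(rng.standard_normal((64, 32, 32)).astype(np.float32)),
            p4=Tensor(rng.standard_normal((64, 32, 32)).astype(np.float32)))
        return dec, pyr, dec(pyr)

    def test_ten_mask_sets_at_quarter_scale(self, decoded):
        _, _, state = decoded
        assert len(state.mask_logits) == 10
        for ml in state.mask_logits:
            assert ml.shape == (20, 32, 32)
        for cl in state.class_logits:
            assert cl.shape == (20, 2)

    def test_each_scale_visited_exactly_three_times(self, decoded):
        _, _, state = decoded
        assert state.scales_used == [16, 8, 4] * 3
        assert all(state.scales_used.count(s) == 3 for s in (16, 8, 4))

    def test_zeroed_sublayers_make_x9_equal_x0(self):
        cfg = RunConfig.tiny(n_queries=4, decoder_dim=64)
        rng = np.random.default_rng(1)
        dec = MaskDecoder(cfg, rng)
        for layer in dec.layers:
            for attn in (layer.cross, layer.self_attn):
                attn.proj.weight.data[:] = 0.0
                attn.proj.bias.data[:] = 0.0
            layer.mlp.fc2.weight.data[:] = 0.0
            layer.mlp.fc2.bias.data[:] = 0.0
        pyr = FeaturePyramid(
            g16=Tensor(rng.standard_normal((64, 4, 4)).astype(np.float32)),
            g8=Tensor(rng.standard_normal((64, 8, 8)).astype(np.float32)),
            g4=Tensor(rng.standard_normal((64, 16, 16)).astype(np.float32)),
            p4=Tensor(rng.standard_normal((64, 16, 16)).astype(np.float32)))
        state = dec(pyr)
        np.testing.assert_allclose(state.queries[-1].data, dec.x0.data,
                                   atol=1e-6)

    def test_forward_is_reproducible_for_fixed_seed(self):
        outs = []
        for _ in range(2):
            cfg = RunConfig.tiny(n_queries=8, decoder_dim=64)
            rng = np.random.default_rng(42)
            dec = MaskDecoder(cfg, rng)
            feat_rng = np.random.default_rng(7)
            pyr = FeaturePyramid(
                g16=Tensor(feat_rng.standard_normal((64, 4, 4)).astype(np.float32)),
                g8=Tensor(feat_rng.standard_normal((64, 8, 8)).astype(np.float32)),
                g4=Tensor(feat_rng.standard_normal((64, 16, 16)).astype(np.float32)),
                p4=Tensor(feat_rng.standard_normal((64, 16, 16)).astype(np.float32)))
            outs.append(dec(pyr).final_masks.data)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestPredictMasks:
    def test_hand_computed_inner_products(self, rng):
        cfg = RunConfig.tiny(n_queries=1, decoder_dim=64)
        dec = MaskDecoder(cfg, rng)
        x = Tensor(rng.standard_normal((1, 64)).astype(np.float32))
        p4 = Tensor(rng.standard_normal((64, 2, 2)).astype(np.float32))
        got = dec.predict_masks(x, p4).data
        emb = dec.mask_head(dec.decoder_norm(x)).data[0]
        for y in range(2):
            for xx in range(2):
                np.testing.assert_allclose(got[0, y, xx],
                                           emb @ p4.data[:, y, xx], atol=1e-4)

    def test_orthogonal_embedding_gives_empty_binary_masks(self, rng):
        cfg = RunConfig.tiny(n_queries=2, decoder_dim=64)
        dec = MaskDecoder(cfg, rng)
        # force the mask embedding to zero -> all logits exactly 0
        dec.mask_head.fc3.weight.data[:] = 0.0
        dec.mask_head.fc3.bias.data[:] = 0.0
        x = Tensor(rng.standard_normal((2, 64)).astype(np.float32))
        p4 = Tensor(rng.standard_normal((64, 4, 4)).astype(np.float32))
        logits = dec.predict_masks(x, p4).data
        assert (logits == 0).all()
        assert not (logits > 0).any()  # binarization at >0 keeps nothing


class TestPostprocess:
    def _mask(self, fill):
        m = np.full((1, 8, 8), -10.0, np.float32)
        for (y0, y1, x0, x1) in fill:
            m[0, y0:y1, x0:x1] = 10.0
        return m

    def test_no_confident_query_gives_empty_map(self):
        masks = np.full((3, 8, 8), 10.0, np.float32)
        cls = np.tile([-5.0, 5.0], (3, 1)).astype(np.float32)  # no-object
        inst = postprocess(masks, cls, 16, 16)
        assert inst.count == 0
        assert inst.label_map.n_objects == 0

    def test_two_disjoint_confident_masks_give_two_instances(self):
        masks = np.concatenate([self._mask([(0, 4, 0, 4)]),
                                self._mask([(4, 8, 4, 8)])])
        cls = np.tile([5.0, -5.0], (2, 1)).astype(np.float32)
        inst = postprocess(masks, cls, 16, 16)
        assert inst.count == 2
        assert inst.label_map.n_objects == 2

    def test_nested_masks_overlap_goes_to_higher_score(self):
        """Outer ring + nested square: overlap pixels belong to the
        higher-scoring query, both instances survive."""
        big = self._mask([(0, 8, 0, 8)])
        small = self._mask([(2, 6, 2, 6)])
        masks = np.concatenate([big, small])
        cls = np.array([[2.2, 0.0], [4.0, 0.0]], np.float32)  # small wins
        inst = postprocess(masks, cls, 8, 8)
        assert inst.count == 2
        lab = inst.label_map.labels
        assert lab[4, 4] == 1          # overlap -> higher score, labeled first
        assert lab[0, 0] == 2          # remainder of the big mask survives
        assert inst.scores[0] > inst.scores[1]

    def test_output_satisfies_label_invariants(self, rng):
        masks = rng.standard_normal((6, 8, 8)).astype(np.float32) * 4
        cls = rng.standard_normal((6, 2)).astype(np.float32)
        inst = postprocess(masks, cls, 32, 32)
        inst.label_map.validate()
        assert len(inst.scores) == inst.count
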