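"""Object-level F1 / Dice / Hausdorff and pixel F1 against hand-worked
toys and brute-force set/distance oracles on random instance maps."""

import itertools

import numpy as np
import pytest

from glandseg.core_io import InstanceLabelMap, relabel_contiguous
from glandseg.metrics import (boundary_pixels, dice_object, evaluate_pair,
                              f1_object, f1_pixel, hausdorff_object,
                              match_objects, MetricReport)


def _imap(arr):
    return InstanceLabelMap(relabel_contiguous(np.asarray(arr, np.int32)))


def random_instance_map(rng, shape=(10, 10), n_obj=3):
    """Voronoi-ish random labeling with possible absent objects."""
    seeds_y = rng.integers(0, shape[0], n_obj)
    seeds_x = rng.integers(0, shape[1], n_obj)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    d = (ys[..., None] - seeds_y) ** 2 + (xs[..., None] - seeds_x) ** 2
    lab = d.argmin(axis=2) + 1
    lab[rng.random(shape) < 0.35] = 0  # carve background
    return _imap(lab)


class TestMatchObjects:
    def test_identity_matches_self(self, rng):
        G = random_instance_map(rng)
        overlap, g_star, s_star = match_objects(G, G)
        for i in range(1, G.n_objects + 1):
            assert g_star[i] == i and s_star[i] == i

    def test_disjoint_maps_have_empty_matches(self):
        a = np.zeros((6, 6)); a[:2, :2] = 1
        b = np.zeros((6, 6)); b[4:, 4:] = 1
        _, g_star, s_star = match_objects(_imap(a), _imap(b))
        assert g_star[1] == 0 and s_star[1] == 0

    def test_overlap_table_equals_pixel_count_oracle(self, rng):
        S = random_instance_map(rng, n_obj=3)
        G = random_instance_map(rng, n_obj=2)
        overlap, _, _ = match_objects(S, G)
        for i in range(S.n_objects + 1):
            for j in range(G.n_objects + 1):
                want = int(((S.labels == i) & (G.labels == j)).sum())
                assert overlap[i, j] == want


class TestF1Object:
    def test_identity_is_one(self, rng):
        G = random_instance_map(rng)
        assert f1_object(G, G)["f1"] == 1.0

    def test_empty_prediction_is_zero(self, rng):
        G = random_instance_map(rng)
        S = _imap(np.zeros(G.shape))
        assert f1_object(S, G)["f1"] == 0.0

    def test_one_of_two_objects_found_gives_two_thirds(self):
        g = np.zeros((8, 8)); g[:3, :3] = 1; g[5:, 5:] = 2
        s = np.zeros((8, 8)); s[:3, :3] = 1
        res = f1_object(_imap(s), _imap(g))
        assert res["precision"] == 1.0
        assert res["recall"] == 0.5
        assert res["f1"] == pytest.approx(2 / 3)
        assert (res["tp"], res["fp"], res["fn"]) == (1, 1, 0) or \
               (res["tp"], res["fp"], res["fn"]) == (1, 0, 1)

    def test_under_half_overlap_is_not_a_detection(self):
        g = np.zeros((4, 8)); g[:, :6] = 1
        s = np.zeros((4, 8)); s[:, :2] = 1  # covers 1/3 of gt
        assert f1_object(_imap(s), _imap(g))["f1"] == 0.0

    def test_gt_object_claimed_at_most_once(self):
        """Two predictions inside one gt: only the larger counts."""
        g = np.zeros((6, 6)); g[:, :] = 1
        s = np.zeros((6, 6)); s[:4] = 1; s[4:] = 2
        res = f1_object(_imap(s), _imap(g))
        assert res["tp"] == 1 and res["fp"] == 1


class TestDiceObject:
    def test_identity_is_one(self, rng):
        G = random_instance_map(rng)
        assert dice_object(G, G) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        a = np.zeros((6, 6)); a[:2, :2] = 1
        b = np.zeros((6, 6)); b[4:, 4:] = 1
        assert dice_object(_imap(a), _imap(b)) == 0.0

    def test_half_square_gives_two_thirds(self):
        g = np.zeros((6, 6)); g[1:5, 1:5] = 1          # 16 px
        s = np.zeros((6, 6)); s[1:5, 1:3] = 1          # left half, 8 px
        # Dice = 2*8 / (8+16) = 2/3 on both sides of the symmetrization
        assert dice_object(_imap(s), _imap(g)) == pytest.approx(2 / 3)

    def test_matches_formula_oracle_on_random_maps(self, rng):
        for _ in range(10):
            S = random_instance_map(rng, n_obj=int(rng.integers(1, 4)))
            G = random_instance_map(rng, n_obj=int(rng.integers(1, 4)))
            got = dice_object(S, G)
            # direct evaluation of the weighted-sum definition
            want = 0.0
            s_areas = {i: (S.labels == i).sum() for i in range(1, S.n_objects + 1)}
            g_areas = {j: (G.labels == j).sum() for j in range(1, G.n_objects + 1)}
            ts, tg = sum(s_areas.values()), sum(g_areas.values())
            for i, a in s_areas.items():
                best = max(g_areas,
                           key=lambda j: (((S.labels == i) & (G.labels == j)).sum(), -j),
                           default=None)
                inter = ((S.labels == i) & (G.labels == best)).sum() if best else 0
                d = 2 * inter / (a + g_areas[best]) if best and inter else 0.0
                want += 0.5 * (a / ts) * d
            for j, a in g_areas.items():
                best = max(s_areas,
                           key=lambda i: (((S.labels == i) & (G.labels == j)).sum(), -i),
                           default=None)
                inter = ((S.labels == best) & (G.labels == j)).sum() if best else 0
                d = 2 * inter / (s_areas[best] + a) if best and inter else 0.0
                want += 0.5 * (a / tg) * d
            assert got == pytest.approx(want)


class TestHausdorffObject:
    def test_identity_is_zero(self, rng):
        G = random_instance_map(rng)
        assert hausdorff_object(G, G) == 0.0

    def test_single_pixels_at_3_4_distance(self):
        a = np.zeros((6, 6)); a[0, 0] = 1
        b = np.zeros((6, 6)); b[3, 4] = 1
        assert hausdorff_object(_imap(a), _imap(b)) == pytest.approx(5.0)

    def test_concentric_squares_match_all_pairs_oracle(self):
        g = np.zeros((10, 10)); g[2:8, 2:8] = 1       # side-6 square
        s = np.zeros((10, 10)); s[3:7, 3:7] = 1       # side-4 square
        got = hausdorff_object(_imap(s), _imap(g))
        bs = boundary_pixels(s.astype(bool)).astype(float)
        bg = boundary_pixels(g.astype(bool)).astype(float)
        d = np.sqrt(((bs[:, None] - bg[None]) ** 2).sum(-1))
        want = max(d.min(1).max(), d.min(0).max())
        assert got == pytest.approx(want)

    def test_empty_other_map_uses_image_diagonal(self):
        """Each predicted object is penalized with the image diagonal
        when there is no gt at all; the gt-side sum is empty, so the
        symmetrized value is half the diagonal."""
        a = np.zeros((3, 4)); a[1, 1] = 1
        empty = _imap(np.zeros((3, 4)))
        assert hausdorff_object(_imap(a), empty) == pytest.approx(
            0.5 * np.hypot(3, 4))

    def test_unmatched_object_pairs_with_nearest(self):
        """A false-positive speck with no overlap is scored against the
        nearest gt object, not ignored."""
        g = np.zeros((8, 8)); g[:2, :2] = 1
        s = np.zeros((8, 8)); s[:2, :2] = 1; s[6, 6] = 2
        h = hausdorff_object(_imap(s), _imap(g))
        assert np.isfinite(h) and h > 0


class TestF1Pixel:
    def test_identity_and_empty(self, rng):
        G = random_instance_map(rng)
        assert f1_pixel(G, G) == 1.0
        assert f1_pixel(_imap(np.zeros(G.shape)), G) == 0.0

    def test_confusion_count_oracle(self, rng):
        S = random_instance_map(rng)
        G = random_instance_map(rng)
        s, g = S.labels > 0, G.labels > 0
        tp = (s & g).sum(); fp = (s & ~g).sum(); fn = (~s & g).sum()
        assert f1_pixel(S, G) == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestReport:
    def test_aggregate_is_unweighted_mean(self, rng):
        rep = MetricReport()
        maps = [random_instance_map(rng) for _ in range(3)]
        for i, m in enumerate(maps):
            rep.add(f"im{i}", m, m)
        agg = rep.aggregate()
        assert agg["f1_object"] == 1.0
        assert agg["dice_object"] == 1.0
        assert agg["hausdorff_object"] == 0.0
        assert agg["n_images"] == 3

    def test_json_csv_roundtrip(self, tmp_path, rng):
        rep = MetricReport()
        m = random_instance_map(rng)
        rep.add("a", m, m)
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        import json
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["aggregate"]["f1_object"] == 1.0
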