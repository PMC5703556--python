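"""Multiresolution segmentation against brute-force oracles."""

import math

import numpy as np
import pytest

from crownseg import (
    HeightGrids,
    RuleConfig,
    SceneRaster,
    Transform,
    compute_chm,
    compute_features,
    compute_gv,
    compute_npv,
    merge_objects,
    segment,
)
from crownseg.segmentation import roundness_of_mask

TF = Transform(0.0, 4.0, 0.1)


def make_scene(grid):
    g = np.asarray(grid, dtype=float)
    return SceneRaster(g.copy(), g.copy(), g.copy(), Transform(0.0, g.shape[0] * 0.1, 0.1))


def zero_heights(shape):
    return HeightGrids(dem=np.zeros(shape), dsm=np.zeros(shape))


def oracle_merge_cost(vals_a, vals_b, weights=(1, 1, 1, 1), shape_w=0.1, cmpct=0.5,
                      perim_a=None, perim_b=None, border=0.0, bbox_a=None, bbox_b=None):
    """Independent colour-heterogeneity cost (per-band lists of pixel values).

    Shape terms are omitted when no perimeters are given, matching a
    colour-only comparison with shape_w = 0.
    """
    cost = 0.0
    for w, a, b in zip(weights, vals_a, vals_b):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        m = np.concatenate([a, b])
        cost += w * (m.size * m.std() - a.size * a.std() - b.size * b.std())
    return cost


class TestSegmentOracle:
    def test_uniform_image_single_object(self):
        scene = make_scene(np.full((40, 40), 77.0))
        seg = segment(scene, zero_heights((40, 40)))
        assert seg.n_objects == 1
        assert (seg.labels == 1).all()

    def test_two_half_planes(self):
        g = np.full((40, 40), 50.0)
        g[:, 20:] = 200.0
        scene = make_scene(g)
        cfg = RuleConfig()
        seg = segment(scene, zero_heights((40, 40)), cfg)
        assert seg.n_objects == 2
        assert len(np.unique(seg.labels[:, :20])) == 1
        assert len(np.unique(seg.labels[:, 20:])) == 1
        # oracle: merging the two final half-plane regions (colour term alone,
        # computed independently) already exceeds scale^2, so the merge is
        # rightly refused
        left = [g[:, :20].ravel()] * 3 + [np.zeros(800)]
        right = [g[:, 20:].ravel()] * 3 + [np.zeros(800)]
        assert (1 - cfg.seg_shape) * oracle_merge_cost(left, right) > cfg.seg_scale**2

    def test_checkerboard_quadrants(self):
        g = np.full((40, 40), 10.0)
        g[:20, 20:] = 100.0
        g[20:, :20] = 180.0
        g[20:, 20:] = 250.0
        seg = segment(make_scene(g), zero_heights((40, 40)))
        assert seg.n_objects == 4
        areas = np.bincount(seg.labels.ravel())[1:]
        assert sorted(areas) == [400, 400, 400, 400]

    def test_deterministic_and_partition(self):
        rng = np.random.default_rng(5)
        g = np.full((48, 48), 100.0)
        for _ in range(6):  # a few bright blobs
            r, c = rng.integers(6, 42, 2)
            rr, cc = np.mgrid[0:48, 0:48]
            g[(rr - r) ** 2 + (cc - c) ** 2 < 20] = rng.uniform(150, 250)
        g += rng.normal(0, 1.0, g.shape)
        scene = make_scene(g)
        a = segment(scene, zero_heights((48, 48)))
        b = segment(scene, zero_heights((48, 48)))
        np.testing.assert_array_equal(a.labels, b.labels)
        assert (a.labels > 0).all()
        a.check_partition(valid=np.ones((48, 48), bool))

    def test_scale_monotonicity(self):
        rng = np.random.default_rng(6)
        g = rng.uniform(0, 255, (32, 32)).round()
        scene = make_scene(g)
        counts = [
            segment(scene, zero_heights((32, 32)), scale=s).n_objects
            for s in (5, 10, 20, 40, 80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            segment(make_scene(np.ones((4, 4))), zero_heights((4, 4)), weights=[0, 0, 0, 0])


class TestFeatures:
    @staticmethod
    def featured_map(grid, chm=None):
        scene = make_scene(grid)
        shape = scene.shape
        h = HeightGrids(dem=np.zeros(shape), dsm=chm if chm is not None else np.zeros(shape))
        h = compute_chm(h)
        seg = segment(scene, h)
        return compute_features(seg, scene, h, compute_gv(scene), compute_npv(scene))

    def test_constant_grid_single_object_means(self):
        seg = self.featured_map(np.full((10, 10), 42.0))
        row = seg.table.iloc[0]
        assert row["area_px"] == 100
        assert row["mean_blue"] == pytest.approx(42.0)
        assert row["mean_gv"] == pytest.approx(0.0)
        assert row["sd_green"] == pytest.approx(0.0)

    def test_means_match_bruteforce_on_random_objects(self):
        rng = np.random.default_rng(7)
        g = np.where(rng.random((30, 30)) < 0.5, 40.0, 200.0)  # many small objects
        seg = self.featured_map(g, chm=rng.uniform(0, 5, (30, 30)))
        h = seg.grids["heights"]
        labels = seg.labels
        for lab, row in seg.table.iterrows():
            mask = labels == lab
            # independent per-pixel accumulation
            assert row["area_px"] == mask.sum()
            assert row["mean_blue"] == pytest.approx(g[mask].mean(), rel=1e-12)
            assert row["sd_blue"] == pytest.approx(g[mask].std(), abs=1e-9)
            assert row["mean_chm"] == pytest.approx(h.chm[mask].mean(), rel=1e-12)
            assert row["max_chm"] == pytest.approx(h.chm[mask].max())

    def test_neighbour_borders_symmetric(self):
        rng = np.random.default_rng(8)
        g = np.where(rng.random((20, 20)) < 0.5, 40.0, 200.0)
        seg = self.featured_map(g)
        for a, nbs in seg.neighbors.items():
            for b, length in nbs.items():
                assert seg.neighbors[b][a] == length

    def test_disc_roundness_near_ideal_circle(self):
        rr, cc = np.mgrid[0:81, 0:81]
        disc = (rr - 40) ** 2 + (cc - 40) ** 2 <= 30**2
        # ideal circle scores 0 on the deviation-from-circle metric
        assert roundness_of_mask(disc) == pytest.approx(0.0, abs=0.05)

    def test_elongated_shape_less_round_than_disc(self):
        bar = np.zeros((20, 200), bool)
        bar[5:15, 5:195] = True
        rr, cc = np.mgrid[0:41, 0:41]
        disc = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        assert roundness_of_mask(bar) > roundness_of_mask(disc)


class TestMergeObjects:
    @staticmethod
    def quadrant_map():
        g = np.full((20, 20), 10.0)
        g[:10, 10:] = 100.0
        g[10:, :10] = 180.0
        g[10:, 10:] = 250.0
        return TestFeatures.featured_map(g)

    def test_area_additive_and_weighted_mean(self):
        seg = self.quadrant_map()
        a, b = 1, 2
        area_a = seg.table.at[a, "area_px"]
        area_b = seg.table.at[b, "area_px"]
        mean_a = seg.table.at[a, "mean_blue"]
        mean_b = seg.table.at[b, "mean_blue"]
        merge_objects(seg, a, b)
        assert seg.table.at[a, "area_px"] == area_a + area_b
        expect = (area_a * mean_a + area_b * mean_b) / (area_a + area_b)
        assert seg.table.at[a, "mean_blue"] == pytest.approx(expect)

    def test_smaller_label_survives_and_old_label_unknown(self):
        seg = self.quadrant_map()
        merge_objects(seg, 2, 1)
        assert 2 not in seg.table.index
        with pytest.raises(KeyError):
            merge_objects(seg, 2, 3)

    def test_non_adjacent_merge_rejected(self):
        seg = self.quadrant_map()
        # quadrants 1 (top-left) and 4 (bottom-right) touch only diagonally
        with pytest.raises(ValueError, match="not adjacent"):
            merge_objects(seg, 1, 4)
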