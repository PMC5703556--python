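"""Synthetic scene generator: determinism, signatures, truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from crownseg import RuleConfig, SceneSpec, generate_scene, truth_plot_counts
from crownseg.synthetic import GroundTruth
from crownseg.types import GroundTruthTree, Transform


def tiny_spec(**kw):
    base = dict(
        rng_seed=11,
        extent_m=(45.0, 45.0),
        n_sapote=3,
        n_algarrobo_alive=3,
        n_algarrobo_dead=1,
        dead_cluster_size=0,
        n_overo=2,
        border_margin_m=8.0,
        plot_margin_m=2.0,
    )
    base.update(kw)
    return SceneSpec(**base)


def test_same_seed_bit_identical():
    s1, h1, t1 = generate_scene(tiny_spec())
    s2, h2, t2 = generate_scene(tiny_spec())
    np.testing.assert_array_equal(s1.blue, s2.blue)
    np.testing.assert_array_equal(s1.rededge, s2.rededge)
    np.testing.assert_array_equal(h1.dsm, h2.dsm)
    np.testing.assert_array_equal(t1.mask, t2.mask)


def test_different_seed_differs():
    s1, _, _ = generate_scene(tiny_spec())
    s2, _, _ = generate_scene(tiny_spec(rng_seed=13))
    assert not np.array_equal(s1.blue, s2.blue)


def test_requested_counts_and_masks():
    _, _, truth = generate_scene(tiny_spec())
    species = pd.Series([t.species for t in truth.trees]).value_counts()
    assert species["sapote"] == 3
    assert species["algarrobo"] == 4
    assert species["overo"] == 2
    ids = {t.id for t in truth.trees}
    assert set(np.unique(truth.mask)) - {0} == ids  # every truth tree has a mask
    for t in truth.trees:
        assert t.crown_spread_m2 == pytest.approx(
            truth.mask_of(t.id).sum() * 0.083**2, rel=1e-9
        )


def test_zero_trees_background_only():
    spec = tiny_spec(n_sapote=0, n_algarrobo_alive=0, n_algarrobo_dead=0, n_overo=0)
    scene, heights, truth = generate_scene(spec)
    assert truth.trees == []
    assert (truth.mask == 0).all()
    assert np.allclose(heights.dsm, heights.dem, atol=0.2)  # only DSM noise


def test_sapote_only_scene_respects_gv_threshold():
    spec = tiny_spec(n_sapote=5, n_algarrobo_alive=0, n_algarrobo_dead=0, n_overo=0,
                     noise_sd=0.0, height_noise_sd=0.0)
    scene, _, truth = generate_scene(spec)
    assert len(truth.trees) == 5
    gv = (scene.rededge - scene.green) / (scene.rededge + scene.green)
    for t in truth.trees:
        assert gv[truth.mask_of(t.id)].mean() > 0.08


def test_rendered_means_respect_rule_orderings():
    """Noise-free class means must sit on the right side of every threshold."""
    cfg = RuleConfig()
    spec = tiny_spec(noise_sd=0.0, height_noise_sd=0.0, n_algarrobo_dead=1)
    scene, heights, truth = generate_scene(spec)
    gv = (scene.rededge - scene.green) / (scene.rededge + scene.green)
    npv = (scene.blue - scene.green) / (scene.blue + scene.green)
    chm = heights.dsm - heights.dem
    for t in truth.trees:
        m = truth.mask_of(t.id)
        if t.species == "sapote":
            assert gv[m].mean() >= cfg.sapote_gdvi_min
        elif t.species == "algarrobo" and t.health_grade in (1, 2):
            assert cfg.gdvi_threshold < gv[m].mean() < cfg.sapote_gdvi_min
        else:  # dead algarrobo, overo
            assert npv[m].mean() > cfg.npv_threshold
            if t.species == "overo":
                assert chm[m].max() < cfg.chm_bush_max_m
            else:
                assert chm[m].max() > cfg.chm_bush_max_m
    bg = truth.mask == 0
    assert gv[bg].mean() < cfg.gdvi_threshold
    assert npv[bg].mean() < cfg.npv_threshold


def test_total_crown_area_equals_sum_of_masks():
    _, _, truth = generate_scene(tiny_spec())
    per_tree = sum(int(truth.mask_of(t.id).sum()) for t in truth.trees)
    assert per_tree == int((truth.mask > 0).sum())  # masks are disjoint


def test_invalid_profiles_rejected():
    with pytest.raises(ValueError, match="sapote"):
        spec = tiny_spec()
        from crownseg.synthetic import ClassProfile

        spec.profiles["sapote"] = ClassProfile(60.0, 100.0, 101.0)  # GV too low
        spec.validate()


class TestTruthPlotCounts:
    @staticmethod
    def make_truth(trees):
        plots = pd.DataFrame(
            [{"plot_id": 1, "x0": 0.0, "y0": 0.0, "x1": 10.0, "y1": 10.0}]
        )
        return GroundTruth(
            trees=trees, mask=np.zeros((1, 1), np.int32), plots=plots,
            transform=Transform(0, 10, 0.1),
        )

    def test_health_grade_mapping(self):
        trees = [
            GroundTruthTree(i + 1, "algarrobo", 9.0, (5.0, 5.0), 1, health_grade=g)
            for i, g in enumerate([1, 2, 3])
        ]
        counts = truth_plot_counts(self.make_truth(trees))
        assert counts.at[1, "algarrobo_alive"] == 2
        assert counts.at[1, "algarrobo_dead"] == 1

    def test_small_crown_excluded(self):
        trees = [
            GroundTruthTree(1, "sapote", 3.0, (5.0, 5.0), 1),
            GroundTruthTree(2, "sapote", 4.5, (5.0, 5.0), 1),
        ]
        counts = truth_plot_counts(self.make_truth(trees))
        assert counts.at[1, "sapote"] == 1

    def test_outside_all_plots_uncounted(self):
        trees = [GroundTruthTree(1, "sapote", 9.0, (50.0, 50.0), 1)]
        counts = truth_plot_counts(self.make_truth(trees))
        assert counts.to_numpy().sum() == 0

    def test_overo_counted_as_patches_not_trees(self):
        trees = [GroundTruthTree(1, "overo", 9.0, (5.0, 5.0), 1)]
        counts = truth_plot_counts(self.make_truth(trees))
        assert counts.at[1, "overo_patches"] == 1
        assert counts.at[1, "sapote"] == 0


def test_scene_spec_yaml_round_trip(tmp_path):
    spec = tiny_spec()
    p = tmp_path / "spec.yaml"
    spec.to_yaml(p)
    back = SceneSpec.from_yaml(p)
    assert back == spec
    s1, _, _ = generate_scene(spec)
    s2, _, _ = generate_scene(back)
    np.testing.assert_array_equal(s1.blue, s2.blue)
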