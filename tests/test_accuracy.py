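"""Accuracy machinery: detection rates, error matrix, adjustments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crownseg import (
    adjust_counts,
    build_error_matrix,
    detection_rates,
    ground_truth_reference,
    matrix_stats,
)
from crownseg.classify import CLASSES
from crownseg import reference_survey as rs


class TestDetectionRates:
    def test_published_survey_rates(self):
        rep = detection_rates(rs.DETECTION_CLASSIFIED, rs.DETECTION_REFERENCE)
        assert rep.rate("sapote") == pytest.approx(94.73684, abs=1e-4)
        assert rep.rate("algarrobo_alive") == pytest.approx(115.6863, abs=1e-3)
        assert rep.rate("algarrobo_dead") == pytest.approx(83.90805, abs=1e-4)
        assert rep.overall_rate == pytest.approx(95.3271, abs=1e-4)
        assert rep.table.at["total", "difference"] == -10

    def test_identity_when_counts_match(self):
        counts = {"sapote": 5, "algarrobo_alive": 7, "algarrobo_dead": 2}
        rep = detection_rates(counts, dict(counts))
        assert (rep.table["rate_pct"] == 100.0).all()

    def test_plotwise_frames_are_summed(self):
        idx = pd.Index([1, 2], name="plot_id")
        cl = pd.DataFrame({"sapote": [3, 2], "algarrobo_alive": [1, 1],
                           "algarrobo_dead": [0, 1]}, index=idx)
        ref = pd.DataFrame({"sapote": [4, 2], "algarrobo_alive": [1, 1],
                            "algarrobo_dead": [1, 1]}, index=idx)
        rep = detection_rates(cl, ref)
        assert rep.table.at["sapote", "classified"] == 5
        assert rep.table.at["sapote", "reference"] == 6

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero reference"):
            detection_rates({"sapote": 1, "algarrobo_alive": 1, "algarrobo_dead": 1},
                            {"sapote": 0, "algarrobo_alive": 1, "algarrobo_dead": 1})


class TestAdjustCounts:
    def test_published_adjustments(self):
        rep = detection_rates(rs.DETECTION_CLASSIFIED, rs.DETECTION_REFERENCE)
        adj = adjust_counts(rs.RAW_MAP_COUNTS, rep, area_ha=80.0)
        assert adj.at["sapote", "adjusted"] == 784
        assert adj.at["algarrobo_dead", "adjusted"] == 601
        # the published alive-Algarrobo cell (1122) does not follow this rule
        assert adj.at["algarrobo_alive", "adjusted"] == 1151

    def test_rate_100_is_identity(self):
        adj = adjust_counts({"sapote": 99}, {"sapote": 1.0})
        assert adj.at["sapote", "adjusted"] == 99

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            adjust_counts({"sapote": 1}, {"sapote": 0.0})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ref=st.integers(min_value=1, max_value=500),
        cl=st.integers(min_value=1, max_value=500),
    )
    def test_inverse_of_detection_rate_up_to_rounding(self, ref, cl):
        """Adjusting the classified count by its own rate recovers the reference."""
        counts = {"sapote": cl, "algarrobo_alive": 1, "algarrobo_dead": 1}
        refs = {"sapote": ref, "algarrobo_alive": 1, "algarrobo_dead": 1}
        rep = detection_rates(counts, refs)
        adj = adjust_counts({"sapote": cl}, rep)
        assert adj.at["sapote", "adjusted"] == ref


class TestErrorMatrix:
    def test_all_diagonal(self):
        em = build_error_matrix([("sapote", "sapote")] * 3)
        assert em.counts.at["sapote", "sapote"] == 3
        assert em.grand_total == 3

    def test_empty_matrix_is_zero(self):
        em = build_error_matrix([])
        assert (em.counts.to_numpy() == 0).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            build_error_matrix([("sapote", "cactus")])

    def test_survey_samples_rebuild_printed_matrix(self):
        em = build_error_matrix(rs.error_matrix_samples())
        pd.testing.assert_frame_equal(em.counts, rs.error_matrix_frame())
        assert em.grand_total == 441
        assert em.counts.at["sapote", "sapote"] == 67


class TestMatrixStats:
    def test_published_accuracies(self):
        stats = matrix_stats(build_error_matrix(rs.error_matrix_samples()))
        assert stats.at["overall", "overall_accuracy_pct"] == pytest.approx(94.10, abs=5e-3)
        assert stats.at["sapote", "producers_accuracy_pct"] == pytest.approx(88.16, abs=5e-3)
        assert stats.at["sapote", "users_accuracy_pct"] == pytest.approx(100.0)
        assert stats.at["overall", "number_correct"] == 415

    def test_identity_matrix_all_100(self):
        samples = [(c, c) for c in CLASSES]
        stats = matrix_stats(build_error_matrix(samples))
        for c in CLASSES:
            assert stats.at[c, "producers_accuracy_pct"] == 100.0
            assert stats.at[c, "users_accuracy_pct"] == 100.0

    def test_zero_total_class_is_nan_not_zero(self):
        samples = [("sapote", "sapote"), ("overo", "sapote")]
        stats = matrix_stats(build_error_matrix(samples))
        assert np.isnan(stats.at["algarrobo_dead", "producers_accuracy_pct"])
        assert np.isnan(stats.at["overo", "users_accuracy_pct"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(CLASSES), st.sampled_from(CLASSES)),
                    min_size=1, max_size=60))
    def test_overall_is_weighted_mean_of_users_accuracy(self, samples):
        stats = matrix_stats(build_error_matrix(samples))
        users = stats.loc[list(CLASSES), "users_accuracy_pct"]
        weights = stats.loc[list(CLASSES), "classified_total"].astype(float)
        expected = np.nansum(users * weights) / weights.sum()
        assert stats.at["overall", "overall_accuracy_pct"] == pytest.approx(expected)


class TestGroundTruthReference:
    def test_health_mapping_and_filter(self, small_scene):
        _, _, truth = small_scene
        counts, labels = ground_truth_reference(truth)
        for tree in truth.trees:
            if tree.crown_spread_m2 <= 4.0:
                assert tree.id not in labels
            elif tree.species == "algarrobo":
                expect = "algarrobo_dead" if tree.health_grade == 3 else "algarrobo_alive"
                assert labels[tree.id] == expect
        assert counts["sapote"].sum() == sum(
            1 for t in truth.trees if t.species == "sapote" and t.crown_spread_m2 > 4.0
        )
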