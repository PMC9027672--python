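"""Multilevel Otsu: histogram, objective, oracle, thresholds, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentumor.mlt import (
    EnumerationGuardError,
    Histogram,
    ThresholdError,
    ThresholdSet,
    apply_thresholds,
    compute_histogram,
    decode_thresholds,
    exhaustive_mlt,
    otsu_objective,
    total_variance,
)

from conftest import random_histogram


class TestComputeHistogram:
    def test_direct_count_on_tiny_image(self):
        h = compute_histogram(np.array([[0, 1], [1, 3]]), levels=4)
        assert h.counts.tolist() == [1, 2, 0, 1]
        assert h.probabilities.tolist() == [0.25, 0.5, 0.0, 0.25]
        assert h.n_pixels == 4

    def test_constant_image_concentrates_mass(self):
        h = compute_histogram(np.full((8, 8), 5), levels=16)
        assert h.probabilities[5] == 1.0
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_probabilities_sum_to_one(self, seed):
        h = random_histogram(np.random.default_rng(seed))
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)


class TestOtsuObjective:
    def test_uniform_four_level_hand_computation(self, uniform_hist):
        score = otsu_objective(uniform_hist, ThresholdSet((2,), 4))
        assert score.class_probs == (0.5, 0.5)
        assert score.class_means == (0.5, 2.5)
        assert score.global_mean == 1.5
        assert score.between_class_variance == pytest.approx(1.0, abs=1e-12)

    def test_two_spike_hand_computation(self, two_spike_hist):
        score = otsu_objective(two_spike_hist, ThresholdSet((2,), 8))
        assert score.global_mean == pytest.approx(3.5)
        assert score.between_class_variance == pytest.approx(6.25, abs=1e-12)

    def test_constant_image_scores_zero(self):
        h = compute_histogram(np.full((8, 8), 3), levels=8)
        for t in (1, 3, 7):
            assert otsu_objective(h, ThresholdSet((t,), 8)).between_class_variance == 0.0

    def test_empty_classes_contribute_zero(self, two_spike_hist):
        score = otsu_objective(two_spike_hist, ThresholdSet((3, 4), 8))
        assert score.class_probs[1] == 0.0
        assert score.between_class_variance == pytest.approx(6.25)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ThresholdError):
            ThresholdSet((3, 3), 8)
        with pytest.raises(ThresholdError):
            ThresholdSet((0,), 8)
        with pytest.raises(ThresholdError):
            ThresholdSet((8,), 8)


class TestTotalVariance:
    def test_hand_values(self, uniform_hist, two_spike_hist):
        assert total_variance(uniform_hist) == pytest.approx(1.25, abs=1e-12)
        assert total_variance(two_spike_hist) == pytest.approx(6.25, abs=1e-12)

    def test_constant_histogram_is_zero(self):
        h = compute_histogram(np.full((8, 8), 9), levels=16)
        assert total_variance(h) == 0.0


class TestExhaustiveSearch:
    def test_two_spike_ties_break_to_smallest(self, two_spike_hist):
        ts, score = exhaustive_mlt(two_spike_hist, 1)
        assert ts.thresholds == (2,)
        assert score.between_class_variance == pytest.approx(6.25)

    def test_uniform_four_level_optimum(self, uniform_hist):
        ts, score = exhaustive_mlt(uniform_hist, 1)
        assert ts.thresholds == (2,)
        assert score.between_class_variance == pytest.approx(1.0)

    def test_matches_classical_binary_otsu(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(7)
        for _ in range(10):
            h = random_histogram(rng, levels=128)
            ts, _ = exhaustive_mlt(h, 1)
            sk = threshold_otsu(hist=(h.counts, np.arange(128)))
            # skimage labels foreground as strictly-above; same split, offset 1
            assert ts.thresholds[0] == sk + 1

    def test_enumeration_guard(self):
        h = Histogram(np.ones(256, dtype=int), 256)
        with pytest.raises(EnumerationGuardError, match="EPO"):
            exhaustive_mlt(h, 5)

    def test_k_exceeding_occupied_levels_rejected(self, two_spike_hist):
        with pytest.raises(ThresholdError):
            exhaustive_mlt(two_spike_hist, 2)

    @given(st.integers(0, 10**6))
    @settings(max_examples=10, deadline=None)
    def test_monotone_refinement(self, seed):
        h = random_histogram(np.random.default_rng(seed), levels=16)
        best = [exhaustive_mlt(h, k)[1].between_class_variance
                for k in (1, 2, 3)]
        assert best[0] <= best[1] + 1e-12 <= best[2] + 2e-12


class TestApplyThresholds:
    def test_boundary_rule(self):
        img = np.array([[1, 2]])
        labels = apply_thresholds(img, ThresholdSet((2,), 4))
        assert labels.tolist() == [[0, 1]]

    def test_two_threshold_classes(self):
        img = np.array([[0, 1, 2, 3]] * 8)
        labels = apply_thresholds(img, ThresholdSet((1, 3), 4))
        assert labels[0].tolist() == [0, 1, 1, 2]

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 64, (16, 16))
        ts = ThresholdSet((10, 30, 50), 64)
        labels = apply_thresholds(img, ts)
        assert labels.min() >= 0 and labels.max() <= 3
        assert labels.shape == img.shape


class TestVarianceDecomposition:
    @given(st.integers(0, 10**6), st.integers(1, 4))
    @settings(max_examples=40, deadline=None)
    def test_between_plus_within_equals_total(self, seed, k):
        rng = np.random.default_rng(seed)
        h = random_histogram(rng, levels=32)
        ts = ThresholdSet(
            tuple(sorted(rng.choice(np.arange(1, 32), size=k, replace=False))), 32
        )
        score = otsu_objective(h, ts)
        p = h.probabilities
        v = np.arange(32)
        within = 0.0
        for (lo, hi), a, eta in zip(ts.class_edges(), score.class_probs, score.class_means):
            if a > 0:
                within += np.dot(p[lo:hi], (v[lo:hi] - eta) ** 2)
        assert score.between_class_variance + within == pytest.approx(
            total_variance(h), abs=1e-9
        )
        assert score.between_class_variance <= total_variance(h) + 1e-9

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_class_probabilities_and_means_are_consistent(self, seed):
        rng = np.random.default_rng(seed)
        h = random_histogram(rng, levels=32)
        score = otsu_objective(h, ThresholdSet((8, 20), 32))
        assert sum(score.class_probs) == pytest.approx(1.0, abs=1e-12)
        mixture_mean = sum(a * e for a, e in zip(score.class_probs, score.class_means))
        assert mixture_mean == pytest.approx(score.global_mean, abs=1e-9)


class TestDecodeThresholds:
    def test_sorts_rounds_and_resolves_collisions(self):
        ts = decode_thresholds(np.array([30.4, 2.6, 2.1]), 64)
        assert ts.thresholds == (2, 3, 30)

    def test_upper_bound_collision_pushes_down(self):
        ts = decode_thresholds(np.array([63.0, 63.0, 63.0]), 64)
        assert ts.thresholds == (61, 62, 63)

    def test_values_clipped_into_range(self):
        ts = decode_thresholds(np.array([-5.0, 100.0]), 64)
        assert ts.thresholds == (1, 63)
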