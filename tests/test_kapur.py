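"""Histogram construction and Kapur's entropy objective."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mayseg.kapur import (
    Histogram,
    KapurTable,
    ThresholdVector,
    class_entropy,
    compute_histogram,
    exhaustive_best_thresholds,
    kapur_objective,
)

from conftest import make_mixture_hist


class TestComputeHistogram:
    def test_two_value_image(self):
        img = np.array([[0, 0], [255, 255]])
        h = compute_histogram(img)
        assert h.probs[0] == 0.5
        assert h.probs[255] == 0.5
        assert h.probs[1:255].sum() == 0
        assert h.total_pixels == 4

    def test_constant_image(self):
        h = compute_histogram(np.full((5, 5), 7))
        assert h.probs[7] == 1.0
        assert np.count_nonzero(h.counts) == 1

    def test_random_image_counts_and_normalization(self, rng):
        img = rng.integers(0, 256, size=(64, 64))
        h = compute_histogram(img)
        assert h.counts.sum() == 4096
        assert abs(h.probs.sum() - 1.0) < 1e-12
        # direct count oracle on a few levels
        for level in (0, 17, 255):
            assert h.counts[level] == int((img == level).sum())

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.empty((0, 0)))
        with pytest.raises(ValueError):
            compute_histogram(np.array([[300]]))
        with pytest.raises(ValueError):
            compute_histogram(np.array([[-1]]))

    def test_json_round_trip(self, random_hist):
        h2 = Histogram.from_json(random_hist.to_json())
        assert np.array_equal(h2.counts, random_hist.counts)
        assert h2.levels == random_hist.levels


class TestClassEntropy:
    def test_uniform_half_range(self, uniform_hist):
        entropy, mass = class_entropy(uniform_hist, 0, 127)
        assert mass == pytest.approx(0.5, abs=1e-12)
        assert entropy == pytest.approx(math.log(128), abs=1e-10)

    def test_single_bin_class_zero_entropy(self):
        h = Histogram.from_probs(np.eye(256)[40])
        entropy, mass = class_entropy(h, 30, 50)
        assert entropy == 0.0
        assert mass == pytest.approx(1.0)

    def test_zero_mass_class_is_zero(self, uniform_hist):
        h = Histogram.from_probs(np.eye(256)[0])
        entropy, mass = class_entropy(h, 100, 200)
        assert (entropy, mass) == (0.0, 0.0)

    def test_matches_term_by_term_summation(self, rng, random_hist):
        lo, hi = 37, 201
        p = random_hist.probs[lo : hi + 1]
        w = p.sum()
        expected = -sum(q / w * math.log(q / w) for q in p if q > 0)
        entropy, mass = class_entropy(random_hist, lo, hi)
        assert entropy == pytest.approx(expected, abs=1e-10)
        assert mass == pytest.approx(w, abs=1e-12)

    def test_lo_greater_than_hi_rejected(self, uniform_hist):
        with pytest.raises(ValueError):
            class_entropy(uniform_hist, 10, 5)


class TestKapurObjective:
    def test_uniform_midpoint_split(self, uniform_hist):
        T = ThresholdVector((128,))
        score = kapur_objective(uniform_hist, T)
        assert score.value == pytest.approx(2 * math.log(128), abs=1e-10)
        assert score.class_masses == pytest.approx([0.5, 0.5])

    def test_single_spike_any_threshold_is_zero(self):
        h = Histogram.from_probs(np.eye(256)[77])
        for t in ((10,), (100, 200), (50, 120, 190)):
            assert kapur_objective(h, ThresholdVector(t)).value == 0.0

    def test_compositional_equality_with_class_entropy(self, rng):
        for _ in range(20):
            probs = rng.random(256)
            h = Histogram.from_probs(probs / probs.sum())
            t = tuple(sorted(rng.choice(np.arange(1, 256), size=3, replace=False).tolist()))
            score = kapur_objective(h, ThresholdVector(t))
            edges = (0, *t, 256)
            expected = sum(class_entropy(h, a, b - 1)[0] for a, b in zip(edges[:-1], edges[1:]))
            assert score.value == pytest.approx(expected, abs=1e-10)
            assert score.value == pytest.approx(score.per_class_entropies.sum())

    def test_value_invariant_to_total_pixels(self, rng):
        counts = rng.integers(1, 50, size=256)
        h1 = Histogram.from_counts(counts)
        h2 = Histogram.from_counts(counts * 9)
        T = ThresholdVector((60, 170))
        assert kapur_objective(h1, T).value == pytest.approx(kapur_objective(h2, T).value, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_entropy_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.random(256) * (rng.random(256) < 0.5)
        if probs.sum() == 0:
            probs[0] = 1.0
        h = Histogram.from_probs(probs / probs.sum())
        n = int(rng.integers(2, 5))
        t = tuple(sorted(rng.choice(np.arange(1, 256), size=n - 1, replace=False).tolist()))
        score = kapur_objective(h, ThresholdVector(t))
        assert 0.0 <= score.value <= n * math.log(256) + 1e-9
        assert score.class_masses.sum() == pytest.approx(1.0, abs=1e-12)


class TestThresholdVector:
    @pytest.mark.parametrize("bad", [(5, 5), (200, 100), (0,), (256,)])
    def test_invalid_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            ThresholdVector(bad)

    def test_class_bounds_cover_range(self):
        T = ThresholdVector((30, 100, 200))
        bounds = T.class_bounds()
        assert bounds[0][0] == 0 and bounds[-1][1] == 256
        assert all(b[1] == nb[0] for b, nb in zip(bounds, bounds[1:]))


class TestExhaustiveSearch:
    def test_two_spike_histogram(self):
        # Kapur's criterion on two deltas prefers the degenerate split that
        # leaves one empty class (value ln 2 > 0 of any separating split)
        probs = np.zeros(256)
        probs[50] = probs[200] = 0.5
        h = Histogram.from_probs(probs)
        T, score = exhaustive_best_thresholds(h, 2)
        assert score.value == pytest.approx(math.log(2), abs=1e-12)
        assert T.thresholds == (1,)  # lexicographically smallest among ties

    def test_uniform_bilevel_matches_full_scan(self, uniform_hist):
        T, score = exhaustive_best_thresholds(uniform_hist, 2)
        scan = [
            kapur_objective(uniform_hist, ThresholdVector((t,))).value for t in range(1, 256)
        ]
        assert score.value == pytest.approx(max(scan), abs=1e-12)
        assert T.thresholds[0] == int(np.argmax(scan)) + 1

    def test_trilevel_matches_independent_double_loop(self, rng):
        h = make_mixture_hist(rng, n_modes=3)
        T, score = exhaustive_best_thresholds(h, 3)
        best_val, best_t = -np.inf, None
        table = KapurTable(h)
        for t1 in range(1, 255):
            for t2 in range(t1 + 1, 256):
                v = table.entropy(0, t1) + table.entropy(t1, t2) + table.entropy(t2, 256)
                if v > best_val:
                    best_val, best_t = v, (t1, t2)
        assert score.value == pytest.approx(best_val, abs=1e-10)
        assert T.thresholds == best_t

    def test_four_class_search_consistent_with_objective(self, rng):
        h = make_mixture_hist(rng, n_modes=4)
        T, score = exhaustive_best_thresholds(h, 4)
        assert kapur_objective(h, T).value == pytest.approx(score.value, abs=1e-10)

    def test_unsupported_class_count_rejected(self, uniform_hist):
        with pytest.raises(ValueError):
            exhaustive_best_thresholds(uniform_hist, 6)


class TestKapurTable:
    def test_table_matches_objective(self, rng, random_hist):
        table = KapurTable(random_hist)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            t = tuple(sorted(rng.choice(np.arange(1, 256), size=n - 1, replace=False).tolist()))
            assert table.value(t) == pytest.approx(
                kapur_objective(random_hist, ThresholdVector(t)).value, abs=1e-10
            )
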