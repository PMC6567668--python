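"""Ripley K/L estimation, CSR envelopes, classification and simulators.

The K estimator is checked against an independent brute-force double loop
(oracle) for small patterns, both uncorrected and translation-corrected.
"""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from soyco2 import (
    PointPattern,
    Window,
    analyze_pattern,
    classify_scales,
    csr_envelope,
    l_transform,
    ripley_k,
    simulate_cluster,
    simulate_csr,
    simulate_hardcore,
)
from soyco2.errors import AnalysisError, DomainError, PackingError


def brute_force_k(coords, window, distances, correction):
    """Independent O(n^2 * |grid|) reference implementation."""
    n = len(coords)
    area = window.width * window.height
    out = np.zeros(len(distances))
    for k, d in enumerate(distances):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                dx = abs(coords[i][0] - coords[j][0])
                dy = abs(coords[i][1] - coords[j][1])
                if math.hypot(dx, dy) <= d:
                    if correction == "translation":
                        w = area / ((window.width - dx) * (window.height - dy))
                    else:
                        w = 1.0
                    total += w
        out[k] = area * total / (n * (n - 1))
    return out


class TestRipleyKOracle:
    def test_two_point_uncorrected(self):
        w = Window(1.0, 1.0)
        pat = PointPattern(np.array([[0.4, 0.5], [0.6, 0.5]]), w)
        assert ripley_k(pat, [0.25], "none")[0] == pytest.approx(1.0)

    def test_two_point_translation_weight(self):
        # overlap area (1-0.2)*1 = 0.8 -> weight 1.25 per ordered pair
        w = Window(1.0, 1.0)
        pat = PointPattern(np.array([[0.4, 0.5], [0.6, 0.5]]), w)
        assert ripley_k(pat, [0.25], "translation")[0] == pytest.approx(1.25)

    def test_zero_distance_gives_zero(self):
        pat = simulate_csr(20, Window(1, 1), seed=0)
        assert ripley_k(pat, [0.0])[0] == 0.0

    @pytest.mark.parametrize("correction", ["none", "translation"])
    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_brute_force(self, correction, n):
        window = Window(100.0, 80.0)
        pat = simulate_csr(n, window, seed=n)
        grid = np.linspace(0, 40, 21)
        expected = brute_force_k(pat.coords, window, grid, correction)
        np.testing.assert_allclose(
            ripley_k(pat, grid, correction), expected, rtol=1e-12, atol=1e-12
        )

    def test_khat_nondecreasing(self):
        pat = simulate_csr(50, Window(400, 400), seed=5)
        k = ripley_k(pat, np.arange(0, 201, 2))
        assert np.all(np.diff(k) >= -1e-12)

    def test_single_point_rejected(self):
        pat = PointPattern(np.array([[1.0, 1.0]]), Window(10, 10))
        with pytest.raises(AnalysisError):
            ripley_k(pat, [1.0])

    def test_beyond_validity_bound_warns_and_nans(self):
        pat = simulate_csr(10, Window(100, 100), seed=1)
        with pytest.warns(UserWarning, match="truncated"):
            k = ripley_k(pat, [10.0, 80.0])
        assert np.isfinite(k[0]) and np.isnan(k[1])

    def test_scaling_covariance(self):
        # scaling coordinates and window by s maps K(d) -> s^2 K(d/ s scale)
        s = 2.5
        window = Window(100, 100)
        pat = simulate_csr(25, window, seed=9)
        grid = np.linspace(0, 40, 11)
        k1 = ripley_k(pat, grid)
        pat2 = PointPattern(pat.coords * s, Window(100 * s, 100 * s))
        k2 = ripley_k(pat2, grid * s)
        np.testing.assert_allclose(k2, s**2 * k1, rtol=1e-10)
        l1 = l_transform(k1, grid)
        l2 = l_transform(k2, grid * s)
        np.testing.assert_allclose(l2, s * l1, rtol=1e-9, atol=1e-9)


class TestLTransform:
    def test_csr_expectation_cancels(self):
        d = np.linspace(0, 10, 11)
        np.testing.assert_allclose(
            l_transform(math.pi * d**2, d), 0.0, atol=1e-12
        )

    def test_empty_neighborhoods(self):
        assert l_transform([0.0], [10.0])[0] == -10.0

    def test_hand_value(self):
        assert l_transform([4 * math.pi], [1.0])[0] == pytest.approx(1.0)

    def test_negative_khat_rejected(self):
        with pytest.raises(AnalysisError):
            l_transform([-1.0], [1.0])


class TestSimulators:
    def test_csr_empty_and_deterministic(self):
        w = Window(1, 1)
        assert simulate_csr(0, w, seed=0).n == 0
        a = simulate_csr(100, w, seed=42).coords
        b = simulate_csr(100, w, seed=42).coords
        np.testing.assert_array_equal(a, b)

    def test_csr_uniform_moments(self):
        pat = simulate_csr(1000, Window(1, 1), seed=3)
        se = 1.0 / math.sqrt(12 * 1000)
        assert abs(pat.coords[:, 0].mean() - 0.5) < 3 * se
        assert abs(pat.coords[:, 1].mean() - 0.5) < 3 * se

    def test_hardcore_respects_inhibition_distance(self):
        pat = simulate_hardcore(40, Window(400, 400), 30.0, seed=1)
        assert pat.n == 40
        assert pdist(pat.coords).min() >= 30.0

    def test_hardcore_r_zero_is_unconstrained(self):
        pat = simulate_hardcore(50, Window(100, 100), 0.0, seed=2)
        assert pat.n == 50

    def test_hardcore_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            simulate_hardcore(1000, Window(100, 100), 30.0, seed=0)

    def test_cluster_expected_count(self):
        # E[N] = parent_intensity * |W| * mean_offspring (edge losses small
        # for sigma << window); 3 SE tolerance over 100 seeds
        window = Window(400, 400)
        lam, mu, sigma = 5e-4, 6.0, 5.0
        counts = [
            simulate_cluster(lam, mu, sigma, window, seed=s).n for s in range(100)
        ]
        expect = lam * window.area * mu
        se = np.std(counts, ddof=1) / 10
        assert abs(np.mean(counts) - expect) < 3 * se + 0.05 * expect

    def test_cluster_parameter_validation(self):
        with pytest.raises(DomainError):
            simulate_cluster(-1.0, 5.0, 2.0, Window(10, 10))

    def test_duplicate_points_are_jittered(self):
        with pytest.warns(UserWarning, match="jitter"):
            pat = PointPattern(
                np.array([[5.0, 5.0], [5.0, 5.0], [1.0, 1.0]]), Window(10, 10)
            )
        d = pdist(pat.coords)
        assert d.min() > 0
        assert d.min() <= 0.011


class TestEnvelopeAndClassification:
    def test_envelope_brackets_zero_under_csr(self):
        grid = np.linspace(0.02, 0.25, 10)
        low, high = csr_envelope(50, Window(1, 1), grid, n_sims=100, seed=0)
        assert np.all(low < 0) and np.all(high > 0)

    def test_insufficient_simulations_rejected(self):
        with pytest.raises(AnalysisError, match="insufficient"):
            csr_envelope(50, Window(1, 1), [0.1], n_sims=10)

    def test_envelope_deterministic_given_seed(self):
        grid = np.linspace(0.02, 0.2, 5)
        a = csr_envelope(30, Window(1, 1), grid, seed=7)
        b = csr_envelope(30, Window(1, 1), grid, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_classify_all_random(self):
        d = np.arange(5.0)
        labels, rng_ = classify_scales(np.zeros(5), -np.ones(5), np.ones(5), d)
        assert set(labels) == {"random"}
        assert rng_ is None

    def test_classify_strongly_negative_lhat_is_regular(self):
        d = np.array([70.0])
        labels, rr = classify_scales([-12.0], [-2.0], [2.0], d)
        assert labels[0] == "regular"
        assert rr == (70.0, 70.0)

    def test_classify_longest_run_reported(self):
        d = np.arange(6, dtype=float)
        lhat = np.array([0, -5, 0, -5, -5, -5], dtype=float)
        labels, rr = classify_scales(lhat, -np.ones(6), np.ones(6), d)
        assert rr == (3.0, 5.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            classify_scales([0.0], [0.0, 0.0], [0.0, 0.0], [0.0, 1.0])

    def test_hardcore_pattern_classified_regular_at_small_scales(self):
        hits = 0
        runs = 20
        for s in range(runs):
            pat = simulate_hardcore(40, Window(400, 400), 30.0, seed=100 + s)
            res = analyze_pattern(pat, n_sims=50, seed=1000 + s)
            if res.regular_range is not None and res.regular_range[0] <= 30.0:
                hits += 1
        assert hits >= 0.9 * runs

    def test_clustered_pattern_exceeds_upper_envelope(self):
        hits = 0
        usable = 0
        window = Window(400, 400)
        for s in range(20):
            pat = simulate_cluster(2e-4, 8.0, 8.0, window, seed=s)
            if pat.n < 10:
                continue
            usable += 1
            res = analyze_pattern(pat, n_sims=50, seed=500 + s)
            small = res.distances <= 50
            if np.any(res.lhat[small] > res.envelope_high[small]):
                hits += 1
        assert usable >= 15
        assert hits >= 0.9 * usable
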