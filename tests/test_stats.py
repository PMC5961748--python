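"""Statistics tests, with brute-force oracles for the Kuiper machinery.

The oracle computes ECDF excursions by explicit enumeration over a fine
grid plus the sample points, independently of the package's vectorized
implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaspol.fixtures import sample_pairs_linear_response
from vaspol.stats import (
    against_flow,
    directionality_table,
    kuiper_fpp,
    kuiper_one_sample,
    kuiper_statistic,
    kuiper_two_sample,
    kuiper_two_sample_statistic,
    polar_histogram,
    rayleigh_test,
    scalar_product_slopes,
    sensor_analysis,
)


# ---------------------------------------------------------------------------
# independent oracles


def kuiper_V_oracle(u):
    """Brute-force one-sample V: evaluate F_n - F at every sample point
    (both sides of the step) rather than via the sorted-index formula."""
    u = np.sort(np.asarray(u, float))
    n = len(u)

    def ecdf(x):
        return np.sum(u <= x) / n

    grid = np.concatenate([u, u - 1e-12, [0.0, 1.0 - 1e-12]])
    d_plus = max(ecdf(x) - x for x in grid)
    d_minus = max(x - (ecdf(x) - 1 / n) for x in u)  # left limit at sample pts
    return d_plus + d_minus


def kuiper_V2_oracle(a, b):
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))

    def fa(x):
        return np.sum(a <= x) / len(a)

    def fb(x):
        return np.sum(b <= x) / len(b)

    grid = np.concatenate([a, b])
    dp = max(fa(x) - fb(x) for x in grid)
    dm = max(fb(x) - fa(x) for x in grid)
    return dp + dm


class TestAgainstFlow:
    @pytest.mark.parametrize(
        "theta, expected",
        [(180.0, True), (-135.0, True), (135.0, True), (90.0, False), (0.0, False), (-179.9, True)],
    )
    def test_window(self, theta, expected):
        assert against_flow(theta) is expected

    def test_custom_tolerance(self):
        assert against_flow(100.0, tolerance_deg=90.0)
        assert not against_flow(80.0, tolerance_deg=90.0)

    def test_vectorized(self):
        out = against_flow(np.array([180.0, 0.0, -150.0]))
        assert out.tolist() == [True, False, True]


class TestDirectionality:
    def test_small_example(self):
        t = directionality_table(np.array([180.0, 170.0, 90.0, 0.0]))
        assert t.groups["all"] == {"n_cells": 4, "n_against": 2, "ratio": 0.5}

    def test_all_against(self):
        t = directionality_table(np.array([180.0, -180.0 + 1e-9, 179.0]))
        assert t.groups["all"]["ratio"] == 1.0

    def test_uniform_quarter_circle(self):
        rng = np.random.default_rng(12)
        theta = rng.uniform(-180.0, 180.0, 100_000)
        t = directionality_table(theta)
        assert t.groups["all"]["ratio"] == pytest.approx(0.25, abs=0.005)

    def test_uniform_any_tolerance(self):
        rng = np.random.default_rng(13)
        theta = rng.uniform(-180.0, 180.0, 100_000)
        for tol in (20.0, 60.0, 90.0):
            t = directionality_table(theta, tolerance_deg=tol)
            assert t.groups["all"]["ratio"] == pytest.approx(2 * tol / 360, abs=0.006)

    def test_groups_and_empty(self):
        theta = np.array([180.0, 0.0, 170.0])
        g = np.array(["a", "a", "b"])
        t = directionality_table(theta, groups=g)
        assert t.groups["a"]["ratio"] == 0.5
        assert t.groups["b"]["ratio"] == 1.0
        assert sum(v["n_cells"] for k, v in t.groups.items() if k != "all") == 3


class TestKuiperOneSample:
    def test_hand_computed_single_point(self):
        # {0.5}: D+ = D- = 0.5 by hand ECDF
        assert kuiper_statistic(np.array([0.5])) == pytest.approx(1.0)
        r = kuiper_one_sample(np.array([0.0]))  # maps to u = 0.5
        assert r.statistic == pytest.approx(1.0)

    def test_hand_computed_two_points(self):
        assert kuiper_statistic(np.array([0.25, 0.75])) == pytest.approx(0.5)

    def test_oracle_agreement(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            u = rng.random(rng.integers(2, 40))
            assert kuiper_statistic(u) == pytest.approx(kuiper_V_oracle(u), abs=1e-9)

    def test_cyclic_invariance(self):
        rng = np.random.default_rng(22)
        theta = rng.uniform(-180.0, 180.0, 60)
        v0 = kuiper_one_sample(theta).statistic
        for shift in (37.0, 123.4, -88.8):
            shifted = np.mod(theta + shift + 180.0, 360.0) - 180.0
            assert kuiper_one_sample(shifted).statistic == pytest.approx(v0, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            kuiper_one_sample(np.array([]))

    def test_small_n_uses_monte_carlo(self):
        r = kuiper_one_sample(np.array([10.0, 40.0, -30.0]), seed=0)
        assert r.method == "monte_carlo"
        assert 0.0 < r.pvalue <= 1.0

    def test_statistic_range(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            v = kuiper_statistic(rng.random(10))
            assert 0.0 < v <= 2.0

    def test_concentrated_sample_rejects(self):
        rng = np.random.default_rng(24)
        theta = rng.normal(90.0, 5.0, 100)
        r = kuiper_one_sample(theta)
        assert r.pvalue < 1e-6

    def test_calibration_quick(self):
        # 500-rep version of the alpha-calibration check (full 2000 reps
        # runs in the acceptance suite)
        rng = np.random.default_rng(25)
        rejections = 0
        reps = 500
        for _ in range(reps):
            theta = rng.uniform(-180.0, 180.0, 50)
            if kuiper_one_sample(theta).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestKuiperTwoSample:
    def test_identical_samples_minimal(self):
        a = np.array([10.0, 50.0, -90.0, 170.0])
        r = kuiper_two_sample(a, a.copy())
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue > 0.99

    def test_separated_supports_reject(self):
        rng = np.random.default_rng(31)
        a = rng.uniform(0.0, 90.0, 200)
        b = rng.uniform(180.0, 270.0, 200) - 360.0 * (rng.uniform(180.0, 270.0, 200) > 180)
        b = np.mod(b + 180.0, 360.0) - 180.0
        r = kuiper_two_sample(a, b, method="monte_carlo", n_perm=2000, seed=0)
        assert r.pvalue < 0.001

    def test_symmetry(self):
        rng = np.random.default_rng(32)
        a, b = rng.uniform(-180, 180, 30), rng.uniform(-180, 180, 45)
        assert kuiper_two_sample(a, b).statistic == pytest.approx(
            kuiper_two_sample(b, a).statistic
        )

    def test_oracle_agreement(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            a = rng.random(rng.integers(2, 30))
            b = rng.random(rng.integers(2, 30))
            assert kuiper_two_sample_statistic(a, b) == pytest.approx(
                kuiper_V2_oracle(a, b), abs=1e-9
            )

    def test_cyclic_invariance(self):
        rng = np.random.default_rng(34)
        a, b = rng.uniform(-180, 180, 40), rng.uniform(-180, 180, 40)
        v0 = kuiper_two_sample(a, b).statistic
        shifted_a = np.mod(a + 61.0 + 180.0, 360.0) - 180.0
        shifted_b = np.mod(b + 61.0 + 180.0, 360.0) - 180.0
        assert kuiper_two_sample(shifted_a, shifted_b).statistic == pytest.approx(v0, abs=1e-12)

    def test_asymptotic_vs_permutation_agreement(self):
        rng = np.random.default_rng(35)
        for spread in (180.0, 120.0, 90.0):
            a = rng.uniform(-180.0, 180.0, 100)
            b = rng.uniform(-spread, spread, 100)
            pa = kuiper_two_sample(a, b).pvalue
            pp = kuiper_two_sample(a, b, method="monte_carlo", n_perm=3000, seed=1).pvalue
            assert abs(pa - pp) <= 0.02

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            kuiper_two_sample(np.array([]), np.array([1.0]))


class TestRayleigh:
    def test_uniform_not_rejected(self):
        rng = np.random.default_rng(41)
        z, p = rayleigh_test(rng.uniform(-180, 180, 500))
        assert p > 0.01

    def test_concentrated_rejected(self):
        rng = np.random.default_rng(42)
        z, p = rayleigh_test(rng.normal(0.0, 10.0, 100))
        assert p < 1e-6


class TestPolarHistogram:
    def test_counts_sum(self):
        rng = np.random.default_rng(51)
        theta = rng.uniform(-180.0, 180.0, 333)
        h = polar_histogram(theta)
        assert h.counts.sum() == 333
        assert len(h.counts) == 24

    def test_partition_of_circle(self):
        h = polar_histogram(np.array([180.0, -180.0 + 1e-9, 0.0, -90.0]))
        assert h.counts.sum() == 4
        assert h.bin_edges_deg[0] == -180.0
        assert h.bin_edges_deg[-1] == 180.0

    def test_folded(self):
        h = polar_histogram(np.array([-170.0, 170.0, 10.0]), n_bins=2, folded=True)
        assert h.counts.tolist() == [1, 2]


class TestSensorAnalysis:
    def test_linear_response_threshold_recovery(self):
        tau, theta = sample_pairs_linear_response(5000, seed=0)
        curve = sensor_analysis(tau, theta, n_bins=8)
        assert curve.threshold_tau is not None
        assert curve.threshold_tau == pytest.approx(2.0, abs=0.2)

    def test_all_against_smallest_bin_median(self):
        rng = np.random.default_rng(61)
        tau = rng.uniform(0.5, 3.0, 200)
        theta = np.full(200, 175.0)
        curve = sensor_analysis(tau, theta, n_bins=4)
        assert np.all(curve.fraction_against == 1.0)
        assert curve.threshold_tau == pytest.approx(np.min(curve.bin_median_tau))

    def test_never_crosses_undefined(self):
        rng = np.random.default_rng(62)
        tau = rng.uniform(0.0, 3.0, 200)
        theta = np.zeros(200)
        curve = sensor_analysis(tau, theta, n_bins=4)
        assert curve.threshold_tau is None
        assert "never" in curve.threshold_note

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match="fewer bins"):
            sensor_analysis(np.ones(4), np.zeros(4), n_bins=8)

    def test_fractions_brute_force_recomputable(self):
        tau, theta = sample_pairs_linear_response(1000, seed=3)
        curve = sensor_analysis(tau, theta, n_bins=5)
        ag = np.abs(theta) >= 135.0
        for b in range(len(curve.bin_edges) - 1):
            lo, hi = curve.bin_edges[b], curve.bin_edges[b + 1]
            sel = (tau >= lo) & (tau < hi) if b < len(curve.bin_edges) - 2 else (tau >= lo)
            if sel.sum() == 0:
                continue
            assert curve.fraction_against[b] == pytest.approx(ag[sel].mean())
            assert curve.n_per_bin[b] == sel.sum()

    def test_equal_width_binning(self):
        tau, theta = sample_pairs_linear_response(2000, seed=4)
        curve = sensor_analysis(tau, theta, n_bins=6, binning="width")
        assert np.allclose(np.diff(curve.bin_edges), np.diff(curve.bin_edges)[0])

    def test_bin_counts_partition(self):
        tau, theta = sample_pairs_linear_response(999, seed=5)
        curve = sensor_analysis(tau, theta, n_bins=8)
        assert curve.n_per_bin.sum() == 999


class TestScalarProductSlopes:
    def test_exactly_antiparallel(self):
        rng = np.random.default_rng(71)
        t = rng.uniform(0.1, 3.0, 50)
        s = -0.5 * t  # p antiparallel to t with ||p|| = 0.5
        fits = {f.subgroup: f for f in scalar_product_slopes(s, t)}
        neg = fits["negative"]
        assert neg.slope == pytest.approx(-0.5, abs=1e-9)
        assert neg.pearson_r == pytest.approx(-1.0, abs=1e-9)
        assert fits["positive"].slope is None

    def test_aligned_cells(self):
        rng = np.random.default_rng(72)
        t = rng.uniform(0.1, 3.0, 50)
        s = 2.0 * t
        fits = {f.subgroup: f for f in scalar_product_slopes(s, t)}
        assert fits["positive"].slope == pytest.approx(2.0, abs=1e-9)
        assert fits["positive"].pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_independent_s_gives_null_slope(self):
        rng = np.random.default_rng(73)
        t = rng.uniform(0.1, 3.0, 4000)
        s = rng.uniform(0.5, 1.5, 4000)  # positive, independent of t
        fits = {f.subgroup: f for f in scalar_product_slopes(s, t)}
        assert abs(fits["positive"].slope) < 0.05
        assert abs(fits["positive"].pearson_r) < 0.05

    def test_small_subgroup_skipped(self):
        fits = {f.subgroup: f for f in scalar_product_slopes(np.array([1.0, -1.0]), np.array([1.0, 1.0]))}
        assert fits["positive"].slope is None
        assert "fewer than 3" in fits["positive"].note

    def test_zero_s_counted_separately(self):
        s = np.array([0.0, 0.0, 1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        t = np.array([1.0, 2.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        fits = scalar_product_slopes(s, t)
        n_pos = next(f.n for f in fits if f.subgroup == "positive")
        n_neg = next(f.n for f in fits if f.subgroup == "negative")
        assert n_pos + n_neg + int(np.sum(s == 0)) == len(s)


angles = st.lists(
    st.floats(min_value=-179.999, max_value=180.0, allow_nan=False),
    min_size=1,
    max_size=40,
)


class TestHypothesisProperties:
    @given(angles)
    @settings(max_examples=60, deadline=None)
    def test_kuiper_statistic_in_range(self, theta):
        v = kuiper_one_sample(np.array(theta), method="asymptotic").statistic
        assert 0.0 < v <= 2.0

    @given(angles, st.floats(min_value=-360.0, max_value=360.0, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_kuiper_cyclic_invariance(self, theta, shift):
        theta = np.array(theta)
        shifted = np.mod(theta + shift + 180.0, 360.0) - 180.0
        v0 = kuiper_one_sample(theta, method="asymptotic").statistic
        v1 = kuiper_one_sample(shifted, method="asymptotic").statistic
        assert v1 == pytest.approx(v0, abs=1e-9)

    @given(angles, st.floats(min_value=1.0, max_value=179.0))
    @settings(max_examples=60, deadline=None)
    def test_directionality_ratio_bounds(self, theta, tol):
        t = directionality_table(np.array(theta), tolerance_deg=tol)
        assert 0.0 <= t.groups["all"]["ratio"] <= 1.0


class TestKuiperFpp:
    def test_bounds(self):
        assert kuiper_fpp(0.0, 100) == 1.0
        assert kuiper_fpp(2.0, 100) < 1e-10
        for v in np.linspace(0.05, 1.5, 20):
            assert 0.0 <= kuiper_fpp(float(v), 50) <= 1.0

    def test_monotone_in_v(self):
        ps = [kuiper_fpp(v, 50) for v in np.linspace(0.1, 1.0, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
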