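import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pulseicp.features import (candidates_from_pulse, compute_features,
                               curvature, detect_candidates, first_derivative,
                               second_derivative, smooth)
from pulseicp.simulate import make_pulse
from pulseicp.types import PulseWaveform


def gaussian_bump(n=400, center=150, width=20, amp=3.0):
    x = np.arange(n, dtype=float)
    return amp * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth(np.full(100, 7.5)), 7.5)

    def test_impulse_kernel_mass(self):
        imp = np.zeros(201)
        imp[100] = 1.0
        L = smooth(imp, sigma=3.0)
        assert abs(L.sum() - 1.0) <= 1e-9
        assert L[100] == L.max()

    def test_no_overshoot(self, rng):
        for _ in range(10):
            sig = rng.normal(0, 1, 300)
            assert np.max(np.abs(smooth(sig))) <= np.max(np.abs(sig)) + 1e-12

    def test_validation(self):
        with pytest.raises(ValueError):
            smooth(np.array([]))
        with pytest.raises(ValueError):
            smooth(np.ones(10), sigma=0)


class TestDerivatives:
    def test_ramp_backward_difference(self):
        m = 0.25
        L = m * np.arange(50, dtype=float)
        Lx = first_derivative(L)
        np.testing.assert_allclose(Lx, -m)
        np.testing.assert_allclose(second_derivative(Lx), 0.0)

    def test_matches_bruteforce_double_difference(self, rng):
        L = rng.normal(0, 1, 120)
        Lxx = second_derivative(first_derivative(L))
        brute = np.array([L[i] - 2 * L[i + 1] + L[i + 2]
                          for i in range(len(L) - 2)])
        np.testing.assert_allclose(Lxx[:-2], brute, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            first_derivative(np.array([1.0]))


class TestCurvature:
    def test_line_has_zero_curvature(self):
        L = 2.0 * np.arange(80, dtype=float) + 5.0
        ch = first_derivative(L)
        assert np.all(curvature(ch, second_derivative(ch)) == 0.0)

    def test_unit_denominator(self):
        np.testing.assert_allclose(curvature(np.zeros(3), np.array([1., -2., 0.5])),
                                   [1.0, -2.0, 0.5])

    def test_matches_elementwise_formula(self, rng):
        Lx = rng.normal(0, 1, 60)
        Lxx = rng.normal(0, 1, 60)
        expect = np.array([b / (1 + a * a) ** 1.5 for a, b in zip(Lx, Lxx)])
        np.testing.assert_allclose(curvature(Lx, Lxx), expect, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            curvature(np.zeros(3), np.zeros(4))


class TestElevationInvariance:
    def test_channels_and_candidates_invariant(self, rng):
        fs = 400.0
        sig = gaussian_bump() + gaussian_bump(center=260, width=30, amp=2.0) \
            + 0.05 * rng.normal(0, 1, 400)
        for shift in (10.0, -3.7, 1234.5):
            a = compute_features(sig)
            b = compute_features(sig + shift)
            np.testing.assert_allclose(a.Lx, b.Lx, atol=1e-9)
            np.testing.assert_allclose(a.Lxx, b.Lxx, atol=1e-9)
            np.testing.assert_allclose(a.K, b.K, atol=1e-9)
            ca = detect_candidates(a, fs)
            cb = detect_candidates(b, fs)
            np.testing.assert_array_equal(ca.indices, cb.indices)


signals = arrays(np.float64, st.integers(20, 120),
                 elements=st.floats(-50, 50, allow_nan=False))


class TestPropertyInvariants:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sig=signals, shift=st.floats(-100, 100, allow_nan=False))
    def test_derivatives_shift_invariant_and_linear(self, sig, shift):
        Lx = first_derivative(sig)
        np.testing.assert_allclose(first_derivative(sig + shift), Lx,
                                   atol=1e-9)
        np.testing.assert_allclose(first_derivative(2.0 * sig), 2.0 * Lx,
                                   atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sig=signals)
    def test_candidates_sorted_and_inside_pulse(self, sig):
        cands = detect_candidates(compute_features(sig), fs=400.0)
        lat = cands.latencies_ms
        assert np.all(np.diff(lat) > 0)
        assert np.all((lat >= 0) & (lat <= len(sig) * 2.5))


class TestDetectCandidates:
    def test_single_bump_one_candidate_at_apex(self):
        fs = 400.0
        ch = compute_features(gaussian_bump())
        cands = detect_candidates(ch, fs)
        assert len(cands) == 1
        assert abs(cands.indices[0] - 150) <= 1

    def test_monotone_ramp_empty(self):
        ch = compute_features(np.linspace(0.0, 10.0, 300))
        assert len(detect_candidates(ch, 400.0)) == 0

    def test_triphasic_pulse_candidates_near_apexes(self, separated_profile):
        wave, apexes = make_pulse(separated_profile,
                                  rng=np.random.default_rng(3))
        cands = candidates_from_pulse(wave)
        assert len(cands) >= 3
        for apex in apexes:
            assert np.min(np.abs(cands.latencies_ms - apex)) <= 10.0

    def test_merged_shoulder_yields_extra_candidate(self):
        # second bump merges into the descending edge of the first
        sig = gaussian_bump(center=150, width=22, amp=3.0) \
            + gaussian_bump(center=205, width=22, amp=1.6)
        cands = detect_candidates(compute_features(sig), 400.0)
        assert len(cands) >= 2

    def test_latencies_strictly_increasing_within_span(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            sig = sum(gaussian_bump(center=g.uniform(60, 340),
                                    width=g.uniform(10, 40),
                                    amp=g.uniform(0.5, 3.0)) for _ in range(4))
            sig = sig + 0.05 * g.normal(0, 1, 400)
            cands = detect_candidates(compute_features(sig), 400.0)
            lat = cands.latencies_ms
            assert np.all(np.diff(lat) > 0)
            assert np.all((lat >= 0) & (lat < 1000.0))

    def test_smoothing_never_adds_candidates(self):
        sig = gaussian_bump(center=120, width=14, amp=3.0) \
            + gaussian_bump(center=185, width=16, amp=2.2) \
            + gaussian_bump(center=300, width=20, amp=1.5)
        counts = []
        for sigma in (1.0, 2.0, 3.0, 5.0, 8.0, 12.0):
            ch = compute_features(sig, sigma=sigma)
            counts.append(len(detect_candidates(ch, 400.0)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
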