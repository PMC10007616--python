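"""Analytic envelope, envelope filtering, entropy chain, impulse conversion."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.signal import savgol_filter

from ddmhsa.pcg_analysis import (
    AnalyticEnvelope,
    ImpulseTrain,
    analytic_transform,
    envelope_filter,
    extract_startpoints,
    impulse_detect,
    normalize_minmax,
    shannon_entropy,
    smooth_entropy,
)
from ddmhsa.signal_io import Waveform

FS = 2000


class TestAnalyticTransform:
    def test_pure_tone_envelope_is_unity(self):
        t = np.arange(FS) / FS
        ae = analytic_transform(Waveform(np.cos(2 * np.pi * 50 * t), FS))
        core = ae.envelope[100:-100]  # FFT edge effects excluded
        assert np.max(np.abs(core - 1.0)) < 0.02

    def test_zero_signal_gives_zero_envelope_without_errors(self):
        ae = analytic_transform(Waveform(np.zeros(500), FS))
        assert not np.any(ae.envelope)
        assert not np.any(ae.phase_cos)

    def test_envelope_dominates_rectified_signal_on_chirp(self):
        from scipy.signal import chirp

        t = np.arange(2 * FS) / FS
        x = chirp(t, 30, 2, 150)
        ae = analytic_transform(Waveform(x, FS))
        assert np.all(ae.envelope >= np.abs(x) - 1e-9)


class TestEnvelopeFilter:
    def test_constant_envelope_is_not_boosted(self):
        n = 1000
        ae = AnalyticEnvelope(np.full(n, 3.0), np.ones(n), FS)
        fe = envelope_filter(ae, delta=2.0, band=None)
        assert fe.threshold_value == pytest.approx(6.0)
        np.testing.assert_allclose(fe.z, fe.mfilt)  # phase_cos = 1

    def test_two_bursts_are_equalized(self):
        # peak 1.0 and peak 0.4 bursts; after EF both region peaks match
        n = 4000
        env = np.zeros(n)
        env[500:700] = 1.0 * np.hanning(200)
        env[2500:2700] = 0.4 * np.hanning(200)
        ae = AnalyticEnvelope(env, np.ones(n), FS)
        fe = envelope_filter(ae, delta=3.0, band=None)
        p1 = fe.z[400:800].max()
        p2 = fe.z[2400:2800].max()
        assert p2 == pytest.approx(p1, rel=0.01)
        assert p2 / 0.4 > 2  # the weak burst really was raised

    def test_delta_zero_boosts_every_positive_region(self):
        n = 2000
        env = np.zeros(n)
        env[200:400] = 0.5 * np.hanning(200)
        env[1200:1400] = 0.25 * np.hanning(200)
        ae = AnalyticEnvelope(env, np.ones(n), FS)
        fe = envelope_filter(ae, delta=0.0, band=None)
        assert fe.threshold_value == 0.0
        assert fe.z[200:400].max() == pytest.approx(0.5, rel=0.01)
        assert fe.z[1200:1400].max() == pytest.approx(0.5, rel=0.01)

    def test_negative_delta_rejected(self):
        ae = AnalyticEnvelope(np.ones(100), np.ones(100), FS)
        with pytest.raises(ValueError):
            envelope_filter(ae, delta=-1.0)

    def test_unboosted_region_z_bounded_by_mfilt(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2 * FS)
        ae = analytic_transform(Waveform(x, FS))
        fe = envelope_filter(ae, delta=50.0)  # threshold far above everything
        assert np.all(np.abs(fe.z) <= np.abs(fe.mfilt) + 1e-9)


class TestShannonEntropy:
    def test_kernel_values_at_anchors(self):
        # input already spanning [0,1]: x_hat == |x|
        se = shannon_entropy(np.array([0.0, 1 / np.e, 1.0]))
        assert se[0] == 0.0
        assert se[1] == pytest.approx(1 / np.e, abs=1e-12)
        assert se[2] == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_maps_to_zero(self):
        assert not np.any(shannon_entropy(np.full(64, 5.0)))

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(2, 200), elements=st.floats(-1e6, 1e6)))
    def test_output_bounded_by_1_over_e(self, x):
        se = shannon_entropy(x)
        assert np.all(se >= 0)
        assert np.all(se <= 1 / np.e + 1e-12)


class TestSmoothEntropy:
    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.linspace(-1, 1, 3000)
        x = 2 * t**3 - t**2 + 0.5 * t - 3
        out = smooth_entropy(x, FS, window_s=0.45, polyorder=3)
        core = slice(500, -500)
        assert np.max(np.abs(out[core] - x[core])) < 1e-8

    def test_effective_window_is_901_samples_at_2khz(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(3000)
        out = smooth_entropy(x, FS, window_s=0.45, polyorder=3)
        np.testing.assert_array_equal(out, savgol_filter(x, 901, 3))

    def test_white_noise_variance_reduced(self):
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(4000)
            out = smooth_entropy(x, FS)
            assert np.var(out) < np.var(x)

    def test_window_not_exceeding_polyorder_rejected(self):
        with pytest.raises(ValueError):
            smooth_entropy(np.ones(100), fs=2, window_s=1.0, polyorder=3)


class TestNormalizeMinmax:
    def test_simple_example(self):
        np.testing.assert_allclose(normalize_minmax([2, 4, 6]), [0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_minmax([5.0, 5.0]), [0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(arrays(np.float64, st.integers(2, 100), elements=st.floats(-1e6, 1e6)))
    def test_range_is_zero_one_for_nonconstant(self, x):
        out = normalize_minmax(x)
        if np.ptp(x) > 0:
            assert out.min() == 0.0
            assert out.max() == pytest.approx(1.0)
        else:
            assert not np.any(out)


class TestImpulseDetect:
    def test_constant_trace_never_fires_at_sigma_5(self):
        it = impulse_detect(np.full(100, 0.5), FS, sigma=5.0)
        assert not np.any(it.impulse)
        assert it.start_indices.size == 0

    def test_sigma_zero_fires_wherever_positive(self):
        nse = np.array([0.0, 0.2, 0.0, 0.7, 0.0])
        it = impulse_detect(nse, FS, sigma=0.0)
        np.testing.assert_array_equal(it.impulse, [0, 1, 0, 1, 0])

    def test_three_rectangular_peaks_give_three_onsets(self):
        nse = np.full(6000, 0.01)
        onsets = [1000, 3000, 5000]
        for o in onsets:
            nse[o : o + 200] = 0.9
        # brute-force oracle: sweep the threshold rule sample by sample
        thr = 5.0 * nse.mean()
        expected = [
            i for i in range(len(nse))
            if nse[i] > thr and (i == 0 or nse[i - 1] <= thr)
        ]
        it = impulse_detect(nse, FS, sigma=5.0)
        assert list(it.start_indices) == expected == onsets

    def test_start_indices_are_exactly_the_rise_transitions(self):
        rng = np.random.default_rng(11)
        nse = np.clip(rng.standard_normal(500), 0, None)
        it = impulse_detect(nse, FS, sigma=1.0)
        imp = it.impulse.astype(int)
        rises = list(np.flatnonzero(np.diff(imp) == 1) + 1)
        if imp[0]:
            rises = [0] + rises
        assert list(it.start_indices) == rises

    def test_explicit_baseline_overrides_trace_mean(self):
        nse = np.array([0.0, 0.5, 0.0, 0.5, 0.0])
        assert impulse_detect(nse, FS, sigma=5.0).start_indices.size == 0
        it = impulse_detect(nse, FS, sigma=5.0, baseline_mean=0.05)
        assert it.start_indices.size == 2

    def test_determinism(self):
        rng = np.random.default_rng(2)
        nse = np.clip(rng.standard_normal(2000), 0, None)
        a = impulse_detect(nse, FS, sigma=1.5)
        b = impulse_detect(nse.copy(), FS, sigma=1.5)
        np.testing.assert_array_equal(a.impulse, b.impulse)
        np.testing.assert_array_equal(a.peak_indices, b.peak_indices)


class TestExtractStartpoints:
    def test_transition_indices_to_times(self):
        it = ImpulseTrain(np.array([0, 0, 1, 1, 0, 1]), np.array([2, 5]), FS, 5.0)
        out = extract_startpoints(it, min_gap_s=0.0)
        np.testing.assert_allclose(out.times, [0.0010, 0.0025])

    def test_all_zeros_gives_empty(self):
        it = ImpulseTrain(np.zeros(10, dtype=int), np.empty(0, dtype=int), FS, 5.0)
        assert extract_startpoints(it).times.size == 0

    def test_high_first_sample_gives_time_zero(self):
        it = ImpulseTrain(np.array([1, 1, 0]), np.array([0]), FS, 5.0)
        assert extract_startpoints(it).times[0] == 0.0

    def test_close_start_points_merged_keeping_first(self):
        idx = np.array([0, 100, 500])  # 0 s, 0.05 s, 0.25 s
        it = ImpulseTrain(np.zeros(600, dtype=int), idx, FS, 5.0)
        out = extract_startpoints(it, min_gap_s=0.1)
        np.testing.assert_allclose(out.times, [0.0, 0.25])

    def test_close_summits_merged_keeping_tallest(self):
        idx = np.array([100, 200, 900])
        heights = np.array([0.4, 0.9, 0.8])
        it = ImpulseTrain(
            np.zeros(1000, dtype=int), idx, FS, 5.0, peak_indices=idx, peak_heights=heights
        )
        out = extract_startpoints(it, min_gap_s=0.1, use_peaks=True)
        np.testing.assert_allclose(out.times, [0.1, 0.45])
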