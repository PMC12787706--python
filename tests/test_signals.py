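import numpy as np
import pytest

from thermovitals import (
    PULSE_BAND_HZ,
    RESPIRATION_BAND_HZ,
    RectROI,
    TimeSeriesSignal,
    average_bilateral,
    bandpass,
    detect_peaks,
    estimate_rate,
    extract_roi_signal,
    generate_ppg,
    invert,
    normalize_cycles,
    rate_from_intervals,
    rate_from_spectrum,
    segment_cycles,
)
from thermovitals.signals import PeakDetectionError

from conftest import make_stack


def sine(freq_hz, duration_s=40.0, fs=60.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return TimeSeriesSignal(amp * np.sin(2 * np.pi * freq_hz * t + phase), fs=fs)


class TestROIExtraction:
    def test_constant_stack_gives_constant_signal(self):
        sig = extract_roi_signal(make_stack(np.full((5, 6, 6), 3.0)), RectROI(1, 1, 4, 4))
        np.testing.assert_array_equal(sig.values, 3.0)
        assert sig.fs == 60.0

    def test_single_pixel_roi_is_that_pixel_trace(self, rng):
        frames = rng.normal(size=(6, 5, 5))
        sig = extract_roi_signal(make_stack(frames), RectROI(2, 3, 3, 4))
        np.testing.assert_array_equal(sig.values, frames[:, 2, 3])

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_signal(make_stack(np.zeros((3, 4, 4))), RectROI(0, 0, 5, 4))

    @pytest.mark.parametrize("bad", [(2, 2, 2, 4), (3, 0, 2, 4), (-1, 0, 2, 2)])
    def test_degenerate_roi_rejected(self, bad):
        with pytest.raises(ValueError):
            RectROI(*bad)


class TestBilateralAverage:
    def test_examples(self):
        a = TimeSeriesSignal([1.0, 3.0], fs=30.0)
        b = TimeSeriesSignal([3.0, 1.0], fs=30.0)
        np.testing.assert_array_equal(average_bilateral(a, b).values, [2.0, 2.0])
        np.testing.assert_array_equal(average_bilateral(a, a).values, a.values)
        np.testing.assert_array_equal(
            average_bilateral(a, invert(a)).values, [0.0, 0.0]
        )

    def test_mismatched_inputs_rejected(self):
        a = TimeSeriesSignal([1.0, 2.0], fs=30.0)
        with pytest.raises(ValueError):
            average_bilateral(a, TimeSeriesSignal([1.0, 2.0], fs=60.0))
        with pytest.raises(ValueError):
            average_bilateral(a, TimeSeriesSignal([1.0, 2.0, 3.0], fs=30.0))


class TestBandpass:
    def test_in_band_tone_passes_nearly_unattenuated(self):
        sig = sine(1.2)
        out = bandpass(sig, *PULSE_BAND_HZ)
        core = slice(120, -120)  # discard 2 s at each edge
        ratio = np.std(out.values[core]) / np.std(sig.values[core])
        assert ratio > 0.95

    def test_stop_band_tone_is_suppressed(self):
        sig = sine(0.05, duration_s=80.0)
        out = bandpass(sig, *RESPIRATION_BAND_HZ)
        assert np.std(out.values) < 0.10 * np.std(sig.values)

    def test_zero_signal_maps_to_zero(self):
        out = bandpass(TimeSeriesSignal(np.zeros(600), fs=60.0), 0.1, 0.4)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(sine(1.0, fs=10.0), 0.8, 6.0)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass(TimeSeriesSignal(np.zeros(10), fs=60.0), 0.1, 0.4)


class TestPeakDetection:
    def test_quarter_hz_sine_gives_ten_peaks_four_seconds_apart(self):
        sig = sine(0.25)
        peaks = detect_peaks(sig, min_separation_s=1.0, min_prominence=0.5)
        assert peaks.size == 10
        np.testing.assert_allclose(np.diff(peaks) / sig.fs, 4.0, atol=0.02)

    def test_monotone_ramp_has_no_peaks(self):
        with pytest.raises(PeakDetectionError):
            detect_peaks(
                TimeSeriesSignal(np.linspace(0, 1, 100), fs=10.0), 0.5, 0.01
            )

    def test_flat_crest_resolves_to_first_index(self):
        v = np.array([0, 1, 1, 0, 0, 1, 0], dtype=float)
        peaks = detect_peaks(TimeSeriesSignal(v, fs=1.0), 0.5, 0.5)
        assert peaks[0] == 1

    def test_invariant_to_additive_constant(self):
        sig = sine(0.25)
        shifted = TimeSeriesSignal(sig.values + 37.0, fs=sig.fs)
        np.testing.assert_array_equal(
            detect_peaks(sig, 1.0, 0.5), detect_peaks(shifted, 1.0, 0.5)
        )

    def test_equivariant_to_time_reversal(self):
        sig = sine(0.25, phase=0.3)
        rev = TimeSeriesSignal(sig.values[::-1].copy(), fs=sig.fs)
        fwd = detect_peaks(sig, 1.0, 0.5)
        bwd = detect_peaks(rev, 1.0, 0.5)
        np.testing.assert_array_equal(np.sort(len(sig) - 1 - bwd), fwd)


class TestRates:
    @pytest.mark.parametrize(
        "interval_s,expected_bpm", [(4.0, 15.0), (1.0, 60.0)]
    )
    def test_rate_from_uniform_intervals(self, interval_s, expected_bpm):
        fs = 60.0
        peaks = np.arange(5) * int(interval_s * fs)
        assert rate_from_intervals(peaks, fs).rate_bpm == pytest.approx(expected_bpm)

    def test_rate_from_mixed_intervals_uses_mean(self):
        fs = 100.0
        peaks = np.array([0, 80, 180])  # intervals 0.8 s and 1.0 s
        assert rate_from_intervals(peaks, fs).rate_bpm == pytest.approx(60 / 0.9)

    def test_spectral_bin_width_is_reciprocal_duration(self):
        est = rate_from_spectrum(sine(0.25, duration_s=40.0), RESPIRATION_BAND_HZ)
        assert est.rate_bpm == pytest.approx(15.0)  # 0.25 Hz is on-bin at 0.025 Hz
        assert est.peak_freq_hz == pytest.approx(0.25)

    def test_constant_signal_has_no_spectral_peak(self):
        with pytest.raises(ValueError, match="peak"):
            rate_from_spectrum(
                TimeSeriesSignal(np.full(2400, 5.0), fs=60.0), RESPIRATION_BAND_HZ
            )

    def test_time_and_frequency_estimates_agree_on_clean_sine(self):
        sig = sine(0.3)
        td = estimate_rate(sig, RESPIRATION_BAND_HZ, "time_domain")
        fd = estimate_rate(sig, RESPIRATION_BAND_HZ, "frequency_domain")
        one_bin_bpm = 60.0 / sig.duration_s
        assert abs(td.rate_bpm - fd.rate_bpm) <= one_bin_bpm

    def test_ppg_reference_path_recovers_both_rates(self, small_cfg):
        ppg = generate_ppg(small_cfg)
        hr = estimate_rate(ppg, PULSE_BAND_HZ, "time_domain")
        rr = estimate_rate(ppg, RESPIRATION_BAND_HZ, "time_domain")
        assert hr.rate_bpm == pytest.approx(small_cfg.heart_rate_bpm, abs=2.0)
        assert rr.rate_bpm == pytest.approx(small_cfg.resp_rate_bpm, abs=1.0)


class TestCycles:
    def test_segmentation_into_equal_cycles(self):
        sig = TimeSeriesSignal(np.arange(201, dtype=float), fs=10.0)
        cycles = segment_cycles(sig, [0, 100, 200])
        assert [len(c) for c in cycles] == [100, 100]

    def test_unequal_cycle_lengths_preserved(self):
        sig = TimeSeriesSignal(np.arange(100, dtype=float), fs=10.0)
        cycles = segment_cycles(sig, [0, 30, 90])
        assert [len(c) for c in cycles] == [30, 60]

    def test_too_few_anchors_rejected(self):
        sig = TimeSeriesSignal(np.arange(10, dtype=float), fs=10.0)
        with pytest.raises(ValueError):
            segment_cycles(sig, [0, 5])

    def test_identical_cycles_have_zero_sd(self):
        c = np.sin(np.linspace(0, 2 * np.pi, 50))
        tpl = normalize_cycles([c, c.copy(), c.copy()])
        np.testing.assert_allclose(tpl.sd_waveform, 0.0, atol=1e-12)
        assert tpl.n_cycles == 3

    def test_single_cycle_mean_is_that_cycle(self):
        c = np.linspace(0, 3.0, 40)
        tpl = normalize_cycles([c], n_points=40)
        np.testing.assert_allclose(tpl.mean_waveform, np.linspace(0, 1, 40), atol=1e-12)
        np.testing.assert_array_equal(tpl.sd_waveform, 0.0)

    def test_mirrored_cycles_average_to_half(self):
        a = np.linspace(0.0, 1.0, 60)
        tpl = normalize_cycles([a, 1.0 - a])
        np.testing.assert_allclose(tpl.mean_waveform, 0.5, atol=1e-12)

    def test_zero_amplitude_cycle_excluded_with_warning(self):
        a = np.linspace(0.0, 1.0, 60)
        with pytest.warns(UserWarning, match="zero amplitude"):
            tpl = normalize_cycles([a, np.full(60, 2.0)])
        assert tpl.n_cycles == 1


class TestInvert:
    def test_involution_and_peak_trough_swap(self):
        sig = sine(0.25)
        np.testing.assert_array_equal(invert(invert(sig)).values, sig.values)
        peaks_of_neg = detect_peaks(invert(sig), 1.0, 0.5)
        troughs = detect_peaks(
            TimeSeriesSignal(-sig.values, fs=sig.fs), 1.0, 0.5
        )
        np.testing.assert_array_equal(peaks_of_neg, troughs)
        zero = TimeSeriesSignal(np.zeros(10), fs=1.0)
        np.testing.assert_array_equal(invert(zero).values, zero.values)
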