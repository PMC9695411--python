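"""Hanning-taper TFR, baseline normalization and peak extraction."""

import numpy as np
import pytest

from pnhmicro import band_average, baseline_normalize, compute_tfr, peak_frequency
from pnhmicro.alignment import TrialMatrix
from pnhmicro.spectral import NormalizationError


def _tm(data, fs=1000.0, t0=-2.0, label="PD+F"):
    data = np.atleast_2d(data)
    n = data.shape[1]
    return TrialMatrix(
        label=label, channel_id="m", fs_hz=fs, window_s=(t0, t0 + n / fs),
        onsets_s=np.zeros(data.shape[0]), shifts_s=np.zeros(data.shape[0]),
        data=data, times=t0 + np.arange(n) / fs, _extended=data, pad_samples=0,
    )


def _sine_trials(freq, n_trials=10, amp=10.0, fs=1000, dur=4.0, t0=-2.0):
    t = t0 + np.arange(int(dur * fs)) / fs
    return np.tile(amp * np.sin(2 * np.pi * freq * t), (n_trials, 1))


class TestComputeTfr:
    def test_pure_sinusoid_concentrates_at_its_bin(self):
        tm = _tm(_sine_trials(100.0))
        tfr = compute_tfr(tm, 0.4)
        assert tfr.freq_resolution_hz == 2.5
        peak_bins = tfr.freqs_hz[np.argmax(tfr.power, axis=0)]
        assert np.all(np.abs(peak_bins - 100.0) <= 2.5)
        # stationary power: constant over time within 5%
        row = tfr.power[np.argmin(np.abs(tfr.freqs_hz - 100.0))]
        assert row.std() / row.mean() < 0.05

    def test_zero_signal_zero_power(self):
        tfr = compute_tfr(_tm(np.zeros((3, 4000))), 0.4)
        assert np.all(tfr.power == 0)

    def test_two_sinusoids_two_peaks(self):
        data = _sine_trials(80.0) + _sine_trials(160.0)
        tfr = compute_tfr(_tm(data), 0.4)
        spectrum = tfr.power.mean(axis=1)
        for f0 in (80.0, 160.0):
            mask = np.abs(tfr.freqs_hz - f0) <= 15
            local_peak = tfr.freqs_hz[mask][np.argmax(spectrum[mask])]
            assert abs(local_peak - f0) <= 2.5

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            compute_tfr(_tm(np.zeros((2, 300))), 0.4)

    def test_time_step_is_5ms(self):
        tfr = compute_tfr(_tm(_sine_trials(100.0, n_trials=2)), 0.4)
        np.testing.assert_allclose(np.diff(tfr.times_s), 0.005)


class TestBaselineNormalize:
    def test_doubled_power_reads_plus_100(self):
        rng = np.random.default_rng(0)
        n_trials, n = 50, 4000
        data = rng.standard_normal((n_trials, n))
        data[:, 2000:] *= np.sqrt(2)  # power doubles at t = 0
        tfr = compute_tfr(_tm(data), 0.4)
        pct = baseline_normalize(tfr, (-2.0, -1.0))
        late = pct.times_s > 0.5
        assert pct.power[:, late].mean() == pytest.approx(100.0, abs=10)

    def test_stationary_noise_fluctuates_about_zero(self):
        # The 1 s baseline holds few independent 400 ms window positions, so
        # per-frequency means keep a sampling error of several percent even
        # with many trials; the global mean is far tighter.
        rng = np.random.default_rng(1)
        data = rng.standard_normal((200, 4000))
        pct = baseline_normalize(compute_tfr(_tm(data), 0.4), (-2.0, -1.0))
        per_freq = pct.power.mean(axis=1)
        assert np.all(np.abs(per_freq) < 15.0)
        assert abs(per_freq.mean()) < 3.0

    def test_baseline_window_mean_is_zero_by_construction(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 4000))
        pct = baseline_normalize(compute_tfr(_tm(data), 0.4), (-2.0, -1.0))
        mask = (pct.times_s >= -2.0) & (pct.times_s <= -1.0)
        np.testing.assert_allclose(pct.power[:, mask].mean(axis=1), 0, atol=1e-9)

    def test_never_below_minus_100(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 4000))
        data[:, 2200:] = 0.0
        pct = baseline_normalize(compute_tfr(_tm(data), 0.4), (-2.0, -1.0))
        assert pct.power.min() >= -100.0

    def test_zero_baseline_power_is_error_naming_frequency(self):
        data = _sine_trials(100.0, n_trials=3)
        data[:, :2000] = 0.0  # silent baseline
        tfr = compute_tfr(_tm(data), 0.4)
        with pytest.raises(NormalizationError):
            baseline_normalize(tfr, (-2.0, -1.0))


class TestBandAverageAndPeak:
    def test_uniform_change_passes_through(self):
        tfr = compute_tfr(_tm(np.ones((2, 4000))), 0.4)
        tfr.power = np.full_like(tfr.power, 50.0)
        _, series = band_average(tfr)
        np.testing.assert_allclose(series, 50.0)

    def test_band_average_equals_direct_sum(self):
        """A +100% burst confined to 90-110 Hz averages to the bin-weighted
        value computed by an explicit sum over the 60-200 Hz axis."""
        tfr = compute_tfr(_tm(np.ones((1, 4000))), 0.4)
        tfr.power = np.zeros_like(tfr.power)
        in_burst = (tfr.freqs_hz >= 90) & (tfr.freqs_hz <= 110)
        tfr.power[in_burst] = 100.0
        _, series = band_average(tfr, (60.0, 200.0))
        expected = sum(
            100.0 if 90 <= f <= 110 else 0.0 for f in tfr.freqs_hz
        ) / tfr.freqs_hz.size
        np.testing.assert_allclose(series, expected)

    def test_flat_spectrum_tie_returns_lowest_frequency(self):
        tfr = compute_tfr(_tm(np.ones((2, 4000))), 0.4)
        tfr.power = np.full_like(tfr.power, 7.0)
        f, v = peak_frequency(tfr, (-0.5, 0.5))
        assert f == tfr.freqs_hz[0] == 60.0
        assert v == 7.0

    def test_band_outside_axis_rejected(self):
        tfr = compute_tfr(_tm(np.ones((2, 4000))), 0.4)
        with pytest.raises(ValueError):
            band_average(tfr, (300.0, 400.0))

    def test_empty_analysis_window_rejected(self):
        tfr = compute_tfr(_tm(np.ones((2, 4000))), 0.4)
        with pytest.raises(ValueError):
            peak_frequency(tfr, (5.0, 6.0))


class TestSpectralGroundTruth:
    def test_synthetic_es_burst_localized_in_time_and_frequency(self, preset1):
        from pnhmicro import generate_ip_series
        from pnhmicro.pipeline import analyze_pattern

        sig, ann, _ = generate_ip_series(
            preset1, 400, 1000, {"ES": 1 / 8}, seed=21
        )
        tm, pct = analyze_pattern(sig, ann, "ES")
        f, v = peak_frequency(pct, (-0.2, 0.2))
        assert abs(f - preset1.es_fast_hz) <= 5.0
        assert v > 100.0  # clearly above baseline
        # change localized to the event epoch, not the baseline
        _, series = band_average(pct)
        base = (pct.times_s >= -1.0) & (pct.times_s <= -0.5)
        ev = np.abs(pct.times_s - 0.105) <= 0.1
        assert series[ev].mean() > 10 * abs(series[base].mean())

    def test_white_noise_power_flat_across_band(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((200, 4000))
        tfr = compute_tfr(_tm(data), 0.4)
        spectrum = tfr.power.mean(axis=1)
        assert spectrum.std() / spectrum.mean() < 0.10
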