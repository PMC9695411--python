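"""Time-frequency characterization of aligned interictal patterns.

Short-time power is computed with a single Hanning taper sliding in 5 ms
steps: a 200 ms window for epileptic spikes (5 Hz resolution) and a 400 ms
window for the longer patterns (2.5 Hz resolution). The frequency grid is
the set of exact DFT bins of the window (multiples of ``1/window_s``), so no
interpolation is involved. Power is averaged across trials first and then
expressed as percentage change against a pre-event baseline,
``100 * (P(f,t) - B(f)) / B(f)``, the usual convention for event-locked
intracranial spectra. The band summary averages
60-200 Hz; the peak-frequency readout averages the map over an analysis
window and takes the argmax over frequency (ties to the lowest frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .alignment import TrialMatrix

STEP_S = 0.005  # sliding-window step
BAND_HZ = (60.0, 200.0)


@dataclass
class TFRMap:
    """Frequency x time map for one pattern; ``kind`` is 'raw' or 'pct'."""

    label: str
    freqs_hz: np.ndarray
    times_s: np.ndarray
    power: np.ndarray  # (n_freq, n_time)
    window_s: float
    n_trials: int
    kind: str = "raw"
    baseline_window_s: tuple[float, float] | None = None

    @property
    def freq_resolution_hz(self) -> float:
        return 1.0 / self.window_s


def compute_tfr(
    tm: TrialMatrix,
    window_s: float,
    fmin_hz: float = BAND_HZ[0],
    fmax_hz: float = BAND_HZ[1],
    step_s: float = STEP_S,
) -> TFRMap:
    """Trial-averaged Hanning-taper power.

    Window centers run every ``step_s`` wherever the full window fits inside
    the epoch (no padding); the frequency grid is every multiple of
    ``1/window_s`` within ``[fmin, fmax]``.
    """
    fs = tm.fs_hz
    n_win = int(round(window_s * fs))
    n_time = tm.data.shape[1]
    if n_win > n_time:
        raise ValueError(
            f"window {window_s}s exceeds the trial length {n_time / fs}s"
        )
    if not 0 < fmax_hz <= fs / 2:
        raise ValueError("frequencies must lie in (0, fs/2]")
    df = 1.0 / window_s
    kmin = int(np.ceil(fmin_hz / df - 1e-9))
    kmax = int(np.floor(fmax_hz / df + 1e-9))
    bins = np.arange(kmin, kmax + 1)
    freqs = bins * df
    step_n = int(round(step_s * fs))
    starts = np.arange(0, n_time - n_win + 1, step_n)
    centers = tm.times[0] + (starts + n_win / 2) / fs
    taper = np.hanning(n_win)
    scale = 2.0 / (fs * np.sum(taper**2))  # one-sided PSD scaling
    power = np.zeros((freqs.size, starts.size))
    for trial in tm.data:
        wins = np.lib.stride_tricks.sliding_window_view(trial, n_win)[::step_n]
        spec = np.fft.rfft(wins * taper, axis=1)[:, bins]
        power += scale * np.abs(spec.T) ** 2
    n_trials = max(tm.data.shape[0], 1)
    power /= n_trials
    return TFRMap(
        label=tm.label,
        freqs_hz=freqs,
        times_s=centers,
        power=power,
        window_s=window_s,
        n_trials=tm.data.shape[0],
    )


class NormalizationError(ValueError):
    """Baseline power is zero at some frequency."""


def baseline_normalize(
    tfr: TFRMap, baseline_window_s: tuple[float, float]
) -> TFRMap:
    """Percentage change against the mean baseline power per frequency."""
    b0, b1 = baseline_window_s
    mask = (tfr.times_s >= b0) & (tfr.times_s <= b1)
    if not np.any(mask):
        raise ValueError(
            f"baseline window {baseline_window_s} holds no window centers "
            f"(time axis {tfr.times_s[0]:.3f}..{tfr.times_s[-1]:.3f}s)"
        )
    baseline = tfr.power[:, mask].mean(axis=1)
    zero = np.where(baseline == 0)[0]
    if zero.size:
        raise NormalizationError(
            f"zero baseline power at {tfr.freqs_hz[zero].tolist()} Hz"
        )
    pct = 100.0 * (tfr.power - baseline[:, None]) / baseline[:, None]
    return replace(
        tfr, power=pct, kind="pct", baseline_window_s=tuple(baseline_window_s)
    )


def band_average(
    tfr: TFRMap, band_hz: tuple[float, float] = BAND_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean across the band's frequency bins -> (times, series)."""
    lo, hi = band_hz
    mask = (tfr.freqs_hz >= lo - 1e-9) & (tfr.freqs_hz <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"band {band_hz} outside the frequency axis")
    return tfr.times_s, tfr.power[mask].mean(axis=0)


def peak_frequency(
    tfr: TFRMap, analysis_window_s: tuple[float, float]
) -> tuple[float, float]:
    """(f_peak, value) of the time-averaged spectrum over the window.

    Ties resolve to the lowest frequency.
    """
    a0, a1 = analysis_window_s
    mask = (tfr.times_s >= a0) & (tfr.times_s <= a1)
    if not np.any(mask):
        raise ValueError(f"analysis window {analysis_window_s} is empty")
    spectrum = tfr.power[:, mask].mean(axis=1)
    i = int(np.argmax(spectrum))  # argmax returns the first (lowest-f) maximum
    return float(tfr.freqs_hz[i]), float(spectrum[i])
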