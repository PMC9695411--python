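"""Event-locked firing-rate estimation and per-unit modulation statistics.

Rates are estimated on a 1 ms grid by Gaussian kernel smoothing of the spike
train around each aligned event onset (10 ms kernel for epileptic spikes,
50 ms for the slower patterns), then reduced to 100 equal bins per trial for
the cluster-based statistics. A unit's engagement with a pattern is
summarized by the Pearson correlation between its average rate and the
average LFP, and by the maximal significant increase/decrease relative to
the pre-event baseline, in percent (a decrease of 100% is complete silence).
Seizure-locked activity is described with rasters and pre/post rate ratios
only -- never with inferential statistics, since seizure counts are tiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps, stats

from .cluster import ClusterResult

RATE_FS = 1000.0
KERNEL_TRUNC_SD = 4.0
N_BINS = 100


@dataclass
class PeriEventRate:
    unit_id: str
    label: str
    rate: np.ndarray        # trials x time, spikes/s on the 1 ms grid
    times: np.ndarray       # relative time axis (s)
    kernel_sigma_s: float
    onsets_s: np.ndarray
    binned: np.ndarray | None = None      # trials x N_BINS
    bin_centers: np.ndarray | None = None

    @property
    def avg_rate(self) -> np.ndarray:
        return self.rate.mean(axis=0)


@dataclass
class UnitIPStats:
    """One unit x pattern summary row: ^%, v%, rho, significant windows."""

    unit_id: str
    label: str
    up_pct: float | None        # None encodes "n.s."
    down_pct: float | None
    rho: float
    rho_status: str
    sig_windows: list[tuple[float, float]] = field(default_factory=list)
    baseline_fr_hz: float = np.nan


def kernel_rate(
    spike_times_s: np.ndarray,
    aligned_onsets_s: np.ndarray,
    window_s: tuple[float, float],
    sigma_s: float,
    unit_id: str = "",
    label: str = "",
    fs_hz: float = RATE_FS,
) -> PeriEventRate:
    """Gaussian-kernel rate per trial on the 1 ms grid, in spikes/s.

    The kernel is a true density (peak ``1/(sigma*sqrt(2*pi))``) truncated at
    ``+-4 sigma``; spikes near epoch edges lose the truncated tail (no
    reflection), so the integral of a trial's rate equals its spike count
    only for spikes at least ``4 sigma`` inside the window.
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    t0, t1 = window_s
    n = int(round((t1 - t0) * fs_hz))
    times = t0 + (np.arange(n) + 0.5) / fs_hz
    spikes = np.asarray(spike_times_s, dtype=float)
    half = int(round(KERNEL_TRUNC_SD * sigma_s * fs_hz))
    kt = np.arange(-half, half + 1) / fs_hz
    kernel = np.exp(-(kt**2) / (2 * sigma_s**2)) / (sigma_s * np.sqrt(2 * np.pi))
    rate = np.zeros((len(aligned_onsets_s), n))
    for i, onset in enumerate(np.asarray(aligned_onsets_s, dtype=float)):
        rel = spikes[(spikes >= onset + t0 - half / fs_hz)
                     & (spikes < onset + t1 + half / fs_hz)] - onset
        if rel.size == 0:
            continue
        counts = np.zeros(n + 2 * half)
        idx = np.floor((rel - t0) * fs_hz).astype(int) + half
        np.add.at(counts, np.clip(idx, 0, counts.size - 1), 1.0)
        smoothed = sps.fftconvolve(counts, kernel, mode="same")
        rate[i] = smoothed[half : half + n]
    return PeriEventRate(
        unit_id=unit_id,
        label=label,
        rate=rate,
        times=times,
        kernel_sigma_s=sigma_s,
        onsets_s=np.asarray(aligned_onsets_s, dtype=float),
    )


def bin_rates(per: PeriEventRate, n_bins: int = N_BINS) -> np.ndarray:
    """Mean rate per bin per trial; the window must divide into equal bins."""
    n = per.rate.shape[1]
    if n % n_bins:
        raise ValueError(f"{n} samples not divisible into {n_bins} bins")
    w = n // n_bins
    binned = per.rate.reshape(per.rate.shape[0], n_bins, w).mean(axis=2)
    per.binned = binned
    per.bin_centers = per.times.reshape(n_bins, w).mean(axis=1)
    return binned


def rate_lfp_correlation(
    avg_rate: np.ndarray, avg_lfp: np.ndarray
) -> tuple[float, str]:
    """Pearson correlation between average rate and average LFP -> (rho, status)."""
    r = np.asarray(avg_rate, dtype=float)
    x = np.asarray(avg_lfp, dtype=float)
    if r.shape != x.shape:
        raise ValueError("avg_rate and avg_lfp must share a time axis")
    if r.std() == 0 or x.std() == 0:
        return np.nan, "undefined: zero variance"
    return float(stats.pearsonr(r, x).statistic), "ok"


def baseline_bins(bin_centers: np.ndarray,
                  baseline_window_s: tuple[float, float]) -> np.ndarray:
    b0, b1 = baseline_window_s
    idx = np.flatnonzero((bin_centers >= b0) & (bin_centers <= b1))
    if idx.size == 0:
        raise ValueError(f"no bins inside baseline window {baseline_window_s}")
    return idx


def modulation_percent(
    per: PeriEventRate,
    result: ClusterResult,
    baseline_window_s: tuple[float, float],
    baseline_fr_hz: float | None = None,
) -> tuple[float | None, float | None]:
    """Maximal significant increase / decrease vs baseline, in percent.

    The baseline is the trial-average rate over the pre-event baseline bins
    (pass ``baseline_fr_hz`` to use an external estimate, e.g. the global
    10-s-window rate, instead). A direction with no significant cluster
    returns None, which the report layer renders as "n.s.".
    """
    if per.binned is None:
        raise ValueError("call bin_rates first")
    avg = per.binned.mean(axis=0)
    if baseline_fr_hz is None:
        baseline_fr_hz = float(avg[baseline_bins(per.bin_centers,
                                                 baseline_window_s)].mean())
    if baseline_fr_hz == 0:
        raise ValueError("baseline firing rate is zero; modulation undefined")
    up_bins = result.significant_bins("up")
    down_bins = result.significant_bins("down")
    up_pct = (
        100.0 * (float(avg[up_bins].max()) - baseline_fr_hz) / baseline_fr_hz
        if up_bins.size
        else None
    )
    down_pct = (
        100.0 * (baseline_fr_hz - float(avg[down_bins].min())) / baseline_fr_hz
        if down_bins.size
        else None
    )
    return up_pct, down_pct


def sig_windows(result: ClusterResult, bin_centers: np.ndarray,
                bin_width_s: float) -> list[tuple[float, float]]:
    """Significant cluster extents as time intervals."""
    return [
        (
            float(bin_centers[c.start_bin] - bin_width_s / 2),
            float(bin_centers[c.end_bin] + bin_width_s / 2),
        )
        for c in result.significant
    ]


@dataclass
class SeizureRaster:
    unit_id: str
    trials: list[np.ndarray]       # per-seizure spike times relative to onset
    window_s: tuple[float, float]
    pre_rate_hz: float
    post_rate_hz: float

    @property
    def ratio(self) -> float:
        return self.post_rate_hz / self.pre_rate_hz if self.pre_rate_hz > 0 else np.inf


def seizure_raster(
    trains: dict[str, np.ndarray],
    seizure_onsets_s: np.ndarray,
    window_s: tuple[float, float] = (-60.0, 60.0),
) -> dict[str, SeizureRaster]:
    """Seizure-locked spike rasters per unit; descriptive pre/post rates only."""
    onsets = np.asarray(seizure_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("at least one seizure annotation required")
    t0, t1 = window_s
    out = {}
    for uid, t in trains.items():
        t = np.asarray(t, dtype=float)
        rows = [t[(t >= on + t0) & (t < on + t1)] - on for on in onsets]
        pre = sum(int(np.sum(r < 0)) for r in rows)
        post = sum(int(np.sum(r >= 0)) for r in rows)
        out[uid] = SeizureRaster(
            unit_id=uid,
            trials=rows,
            window_s=window_s,
            pre_rate_hz=pre / (abs(t0) * onsets.size),
            post_rate_hz=post / (t1 * onsets.size),
        )
    return out
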