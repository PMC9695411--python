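"""Epoching of LFP around annotated events and onset refinement.

Manually annotated onsets carry jitter of tens of milliseconds; averaging
unaligned trials blurs both the mean LFP and the time-frequency maps. Trials
are therefore aligned to the evolving grand average: each iteration shifts
every trial to the lag (within ``+-max_lag_s``) that maximizes its
Pearson-type cross-correlation with the current average, then re-averages,
until shifts stop changing. The per-trial correction is recorded and the
trial is re-cut from the continuous signal at the corrected onset, so no
samples are rolled or padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationTable, SampledSignal, overlaps_any


@dataclass
class TrialMatrix:
    """Events x time epochs at a common rate, time axis relative to onset."""

    label: str
    channel_id: str
    fs_hz: float
    window_s: tuple[float, float]
    onsets_s: np.ndarray          # annotated onsets (s, recording time)
    shifts_s: np.ndarray          # applied correction per trial (s)
    data: np.ndarray              # trials x n_win view of _extended
    times: np.ndarray             # relative time axis (s)
    _extended: np.ndarray = field(repr=False, default=None)
    pad_samples: int = 0
    converged: bool = True

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def average(self) -> np.ndarray:
        return self.data.mean(axis=0)


def epoch(
    signal: SampledSignal,
    annotations: AnnotationTable,
    label: str,
    window_s: tuple[float, float],
    pad_s: float = 0.35,
) -> TrialMatrix:
    """One trial per annotation of ``label`` whose window fits the recording.

    Trials whose window (extended by ``pad_s`` on each side, the headroom the
    aligner may use) leaves the recording, or overlaps an artifact
    annotation, are dropped. An absent label yields an empty matrix with a
    warning rather than an error.
    """
    t0, t1 = window_s
    if t1 <= t0:
        raise ValueError("window must have positive length")
    fs = signal.fs_hz
    pad_n = int(round(pad_s * fs))
    n_win = int(round((t1 - t0) * fs))
    events = annotations.select(label)
    artifacts = annotations.intervals(["artifact"])
    rows, onsets = [], []
    rec_start, rec_end = signal.t0_s, signal.t0_s + signal.duration_s
    for onset in events["start_s"].to_numpy():
        lo, hi = onset + t0 - pad_s, onset + t1 + pad_s
        if lo < rec_start or hi > rec_end:
            continue
        if overlaps_any(artifacts, onset + t0, onset + t1):
            continue
        i0 = int(round((onset + t0 - signal.t0_s) * fs)) - pad_n
        rows.append(signal.samples[i0 : i0 + n_win + 2 * pad_n])
        onsets.append(onset)
    if not rows:
        warnings.warn(f"no usable events with label {label!r}", stacklevel=2)
        extended = np.empty((0, n_win + 2 * pad_n))
    else:
        extended = np.stack(rows)
    times = t0 + np.arange(n_win) / fs
    return TrialMatrix(
        label=label,
        channel_id=signal.channel_id,
        fs_hz=fs,
        window_s=window_s,
        onsets_s=np.asarray(onsets, dtype=float),
        shifts_s=np.zeros(len(onsets)),
        data=extended[:, pad_n : pad_n + n_win],
        times=times,
        _extended=extended,
        pad_samples=pad_n,
    )


def _corr_vs_template(extended: np.ndarray, template: np.ndarray,
                      pad_n: int, max_lag_n: int) -> np.ndarray:
    """Pearson-type correlation of each trial with the template at every lag.

    Returns (trials, 2*max_lag_n+1); lag L means the trial is re-cut L
    samples later than the annotated onset.
    """
    from scipy.signal import fftconvolve

    n_win = template.size
    tc = template - template.mean()
    t_norm = np.linalg.norm(tc)
    # num_l = sum(w_l * tc): template is zero-mean, so per-window mean
    # subtraction does not change the numerator. Computed as a sliding
    # correlation; window norms come from cumulative sums.
    num_all = fftconvolve(extended, tc[::-1][None, :], mode="valid", axes=1)
    s1 = np.cumsum(extended, axis=1)
    s2 = np.cumsum(extended**2, axis=1)
    zeros = np.zeros((extended.shape[0], 1))
    s1 = np.hstack([zeros, s1])
    s2 = np.hstack([zeros, s2])
    win_sum = s1[:, n_win:] - s1[:, :-n_win]
    win_sq = s2[:, n_win:] - s2[:, :-n_win]
    var = np.maximum(win_sq - win_sum**2 / n_win, 0.0)
    den = np.sqrt(var) * t_norm
    sl = slice(pad_n - max_lag_n, pad_n + max_lag_n + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den[:, sl] > 0,
                        num_all[:, sl] / np.maximum(den[:, sl], 1e-30),
                        -np.inf)
    return corr


def _best_lags(corr: np.ndarray, max_lag_n: int) -> np.ndarray:
    """Argmax per trial; ties resolve to the smallest |lag| (negative first)."""
    lags = np.arange(-max_lag_n, max_lag_n + 1)
    order = np.argsort(np.abs(lags), kind="stable")
    reordered = corr[:, order]
    best = np.argmax(reordered, axis=1)
    return lags[order][best]


def align_trials(
    tm: TrialMatrix,
    max_lag_s: float = 0.15,
    max_iter: int = 10,
    tol_samples: int = 1,
) -> TrialMatrix:
    """Iterative template alignment of a trial matrix.

    The template is the current grand average; shifts are bounded to
    ``+-max_lag_s`` relative to the annotated onset at every iteration, so
    the total correction can never exceed the bound. Non-convergence after
    ``max_iter`` returns the best iterate with ``converged=False``.
    """
    if tm.n_trials < 2:
        raise ValueError("alignment requires at least 2 trials")
    fs = tm.fs_hz
    max_lag_n = int(round(max_lag_s * fs))
    if max_lag_n > tm.pad_samples:
        raise ValueError(
            f"max_lag {max_lag_s}s exceeds the epoch padding "
            f"({tm.pad_samples / fs}s); re-epoch with pad_s >= max_lag_s"
        )
    n_win = tm.data.shape[1]
    if max_lag_n >= n_win // 2:
        raise ValueError("max_lag must be less than half the window")
    ext, pad_n = tm._extended, tm.pad_samples
    shifts = np.zeros(tm.n_trials, dtype=int)
    converged = False
    for _ in range(max_iter):
        current = _cut(ext, pad_n, shifts, n_win)
        template = current.mean(axis=0)
        corr = _corr_vs_template(ext, template, pad_n, max_lag_n)
        new_shifts = _best_lags(corr, max_lag_n)
        delta = int(np.max(np.abs(new_shifts - shifts)))
        shifts = new_shifts
        if delta <= tol_samples:
            converged = True
            break
    data = _cut(ext, pad_n, shifts, n_win)
    return TrialMatrix(
        label=tm.label,
        channel_id=tm.channel_id,
        fs_hz=fs,
        window_s=tm.window_s,
        onsets_s=tm.onsets_s + shifts / fs,
        shifts_s=shifts / fs,
        data=data,
        times=tm.times,
        _extended=ext,
        pad_samples=pad_n,
        converged=converged,
    )


def _cut(ext: np.ndarray, pad_n: int, shifts: np.ndarray, n_win: int) -> np.ndarray:
    rows = [ext[i, pad_n + s : pad_n + s + n_win] for i, s in enumerate(shifts)]
    return np.stack(rows) if rows else np.empty((0, n_win))
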