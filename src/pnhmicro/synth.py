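"""Surrogate nodule recordings with known ground truth.

Generates the three interictal pattern (IP) classes seen in microelectrode
recordings of periventricular nodular heterotopia, on top of a 1/f
background:

* **PD+F** -- trains of >= 3 periodic slow waves, each carrying a short
  narrow-band fast-activity burst (60-200 Hz).
* **SD+F** -- a single sporadic slow wave (0.5-4 s) with a prolonged
  superimposed fast-activity burst.
* **ES**   -- a brief sharp transient (50-100 ms) with a superimposed burst.

Slow deflections are raised-cosine lobes; the epileptic-spike transient is a
difference of Gaussians; fast activity is a Hanning-enveloped sinusoid.
These shapes are smooth and band-limited, so the only narrow-band 60-200 Hz
content of an event is its burst -- which makes the preset burst frequency a
clean spectral ground truth for the time-frequency stage.

Unit activity is an inhomogeneous Poisson process sampled by thinning:
``lambda(t) = baseline * prod_k g(t - onset_k)`` where ``g`` is a per-pattern
gain curve (1 outside its support). Inverse (suppressed) units carry
``g <= 1``. Seizures add a sustained multiplicative gain for their duration.

Everything is driven by ``numpy.random.default_rng`` seeds: identical
(config, seed) gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationTable, SampledSignal


class PlacementError(RuntimeError):
    """Requested event rate too high to place events without overlap."""


class UnsupportedPatternError(ValueError):
    """The preset does not define parameters for the requested pattern."""


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodulePreset:
    """Per-nodule synthesis parameters.

    Fast-activity frequencies follow the narrow-band peaks reported for the
    four recorded nodules; intra-train periods follow the per-nodule mean
    inter-deflection intervals (read as milliseconds). Nodule 3 produced no
    sporadic-discharge pattern, so its ``sdf_*`` fields are None and
    requesting SD+F raises :class:`UnsupportedPatternError`.
    """

    nodule_id: int
    pdf_fast_hz: float
    es_fast_hz: float
    sdf_fast_hz: float | None
    pdf_period_s: float = 0.5
    pdf_jitter_frac: float = 0.15
    pdf_n_deflections: int = 4
    sdf_slow_dur_s: float | None = None
    sdf_burst_dur_s: float | None = None
    es_dur_s: float = 0.07
    event_rate_per_s: float = 1 / 20.0  # per-pattern occurrence rate

    def __post_init__(self) -> None:
        for f_hz in (self.pdf_fast_hz, self.es_fast_hz, self.sdf_fast_hz):
            if f_hz is not None and not (60.0 <= f_hz <= 200.0):
                raise ValueError(f"fast-activity frequency {f_hz} outside 60-200 Hz")
        if self.pdf_jitter_frac < 0:
            raise ValueError("pdf_jitter_frac must be >= 0")


#: The four nodules' narrow-band fast-activity peaks (Hz): PD+F 92/135/106/81,
#: ES 102/134/121/97, SD+F 96/111/-/77 (nodule 3 showed no SD+F). Intra-train
#: periods mirror each nodule's mean inter-deflection interval.
NODULE_PRESETS: dict[int, NodulePreset] = {
    1: NodulePreset(1, pdf_fast_hz=92.0, es_fast_hz=102.0, sdf_fast_hz=96.0,
                    pdf_period_s=0.511, sdf_slow_dur_s=0.75, sdf_burst_dur_s=0.5),
    2: NodulePreset(2, pdf_fast_hz=135.0, es_fast_hz=134.0, sdf_fast_hz=111.0,
                    pdf_period_s=0.574, sdf_slow_dur_s=2.0, sdf_burst_dur_s=1.2),
    3: NodulePreset(3, pdf_fast_hz=106.0, es_fast_hz=121.0, sdf_fast_hz=None,
                    pdf_period_s=1.074),
    4: NodulePreset(4, pdf_fast_hz=81.0, es_fast_hz=97.0, sdf_fast_hz=77.0,
                    pdf_period_s=1.0, sdf_slow_dur_s=2.5, sdf_burst_dur_s=1.5),
}

IP_KINDS = ("PD+F", "SD+F", "ES")

# Waveform amplitudes (microvolt) relative to the ~10 uV RMS background.
SLOW_AMP_UV = 90.0
BURST_AMP_UV = 25.0
ES_AMP_UV = 120.0


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def generate_background(
    duration_s: float,
    fs_hz: float,
    pink_exponent: float = 1.0,
    rms_uV: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> SampledSignal:
    """1/f^a background noise with the requested RMS amplitude.

    ``pink_exponent = 0`` gives white noise; the nodule background default is
    a = 1 (pink). Synthesised in the frequency domain by shaping white
    Gaussian noise with ``f**(-a/2)`` and rescaling to ``rms_uV``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs_hz < 1000:
        raise ValueError("fs_hz must be >= 1000")
    if not 0 <= pink_exponent <= 2:
        raise ValueError("pink_exponent must lie in [0, 2]")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    white = rng.standard_normal(n)
    if pink_exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / fs_hz)
        shape = np.ones_like(freqs)
        nz = freqs > 0
        shape[nz] = freqs[nz] ** (-pink_exponent / 2)
        shape[0] = 0.0  # no DC
        x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd > 0:
        x = x * (rms_uV / sd)
    return SampledSignal("micro1", float(fs_hz), x)


# ---------------------------------------------------------------------------
# Event waveforms
# ---------------------------------------------------------------------------

def _raised_cosine(width_s: float, fs_hz: float, amp: float) -> np.ndarray:
    n = max(int(round(width_s * fs_hz)), 3)
    t = np.arange(n) / (n - 1)
    return amp * 0.5 * (1 - np.cos(2 * np.pi * t))


def _burst(freq_hz: float, dur_s: float, fs_hz: float, amp: float,
           phase: float = 0.0) -> np.ndarray:
    n = max(int(round(dur_s * fs_hz)), 3)
    t = np.arange(n) / fs_hz
    env = np.hanning(n)
    return amp * env * np.sin(2 * np.pi * freq_hz * t + phase)


def _add(buf: np.ndarray, start: int, seg: np.ndarray) -> None:
    a = max(start, 0)
    b = min(start + seg.size, buf.size)
    if b > a:
        buf[a:b] += seg[a - start : b - start]


def render_ip_event(
    kind: str,
    preset: NodulePreset,
    fs_hz: float,
    seed: int | np.random.Generator = 0,
    n_deflections: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one event; returns ``(waveform, deflection_times_s)``.

    Deflection times are relative to the start of the returned segment and
    are the ground truth for the periodicity stage.
    """
    rng = np.random.default_rng(seed)
    if kind == "PD+F":
        return _render_pdf(preset, fs_hz, rng, n_deflections)
    if kind == "SD+F":
        if preset.sdf_fast_hz is None or preset.sdf_slow_dur_s is None:
            raise UnsupportedPatternError(
                f"nodule {preset.nodule_id} preset has no SD+F parameters"
            )
        return _render_sdf(preset, fs_hz)
    if kind == "ES":
        return _render_es(preset, fs_hz)
    raise ValueError(f"unknown pattern kind {kind!r}")


def _render_pdf(preset, fs_hz, rng, n_deflections):
    n_defl = n_deflections if n_deflections is not None else preset.pdf_n_deflections
    if n_defl < 3:
        raise ValueError("PD+F requires at least three deflections")
    periods = preset.pdf_period_s * (
        1 + preset.pdf_jitter_frac * rng.standard_normal(n_defl - 1)
    )
    periods = np.clip(periods, 0.3 * preset.pdf_period_s, None)
    defl_times = np.concatenate([[0.0], np.cumsum(periods)])
    lobe_w = min(0.35, 0.7 * preset.pdf_period_s)
    burst_dur = min(0.15, 0.5 * preset.pdf_period_s)
    total = defl_times[-1] + lobe_w + 0.1
    buf = np.zeros(int(round(total * fs_hz)))
    lobe = _raised_cosine(lobe_w, fs_hz, SLOW_AMP_UV)
    half = lobe.size // 2
    for i, td in enumerate(defl_times):
        c = int(round(td * fs_hz)) + half  # deflection peak sits at td + lobe_w/2
        _add(buf, c - half, lobe)
        b = _burst(preset.pdf_fast_hz, burst_dur, fs_hz, BURST_AMP_UV,
                   phase=rng.uniform(0, 2 * np.pi))
        _add(buf, c - b.size // 2, b)
    return buf, defl_times + lobe_w / 2


def _render_sdf(preset, fs_hz):
    dur = preset.sdf_slow_dur_s
    buf = np.zeros(int(round((dur + 0.2) * fs_hz)))
    lobe = _raised_cosine(dur, fs_hz, 1.3 * SLOW_AMP_UV)
    _add(buf, 0, lobe)
    b = _burst(preset.sdf_fast_hz, preset.sdf_burst_dur_s, fs_hz, BURST_AMP_UV)
    _add(buf, int(round(0.1 * fs_hz)), b)  # burst rides the rising slow wave
    return buf, np.array([dur / 2])


def _render_es(preset, fs_hz):
    dur = preset.es_dur_s
    if not 0.05 <= dur <= 0.1:
        raise ValueError("ES duration must lie in 50-100 ms")
    half_n = int(round(1.5 * dur * fs_hz))
    t = np.arange(-half_n, half_n + 1) / fs_hz
    s1, s2 = dur / 5, dur / 2
    wave = ES_AMP_UV * (np.exp(-(t**2) / (2 * s1**2)) - 0.35 * np.exp(-(t**2) / (2 * s2**2)))
    b = _burst(preset.es_fast_hz, 0.1, fs_hz, BURST_AMP_UV)
    buf = wave.copy()
    _add(buf, half_n - b.size // 2, b)
    return buf, np.array([half_n / fs_hz])


# ---------------------------------------------------------------------------
# Event series
# ---------------------------------------------------------------------------

@dataclass
class SynthRecording:
    """A complete surrogate recording with its ground truth."""

    lfp: SampledSignal
    annotations: AnnotationTable
    spikes: dict = field(default_factory=dict)  # unit_id -> np.ndarray of times
    profiles: dict = field(default_factory=dict)  # unit_id -> UnitGainProfile
    deflections: dict = field(default_factory=dict)  # event row index -> times
    seed: int | None = None


def _lognormal_intervals(rng, mode_s, sigma, size):
    # mode of LogNormal(mu, sigma) is exp(mu - sigma^2)
    mu = np.log(mode_s) + sigma**2
    return rng.lognormal(mu, sigma, size=size)


def generate_ip_series(
    preset: NodulePreset,
    duration_s: float,
    fs_hz: float,
    rates: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    pink_exponent: float = 1.0,
    rms_uV: float = 10.0,
    interval_sigma: float = 0.5,
    edge_margin_s: float = 4.0,
    min_separation_s: float = 5.0,
    max_retries: int = 200,
) -> tuple[SampledSignal, AnnotationTable, dict[int, np.ndarray]]:
    """Background plus inserted IP events of each kind.

    ``rates`` maps pattern kind to events per second (default: the preset's
    ``event_rate_per_s`` for each supported kind). Onsets are drawn from a
    log-normal inter-event distribution whose mode is ``1/rate``; events of
    the same kind never overlap, and any two events (of any kind) keep
    ``min_separation_s`` clear so peri-event baselines stay uncontaminated.
    Returns the signal, the exact annotation table, and the per-event
    deflection-time ground truth keyed by annotation row index.
    """
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = {
            k: preset.event_rate_per_s
            for k in IP_KINDS
            if not (k == "SD+F" and preset.sdf_fast_hz is None)
        }
    for k, r in rates.items():
        if r < 0:
            raise ValueError(f"rate for {k} must be >= 0")
    sig = generate_background(duration_s, fs_hz, pink_exponent, rms_uV, rng)
    rows = []
    occupied: list[tuple[float, float]] = []  # [start, end) incl. margin

    def conflicts(onset, end):
        return any(onset < b + min_separation_s and end + min_separation_s > a
                   for a, b in occupied)

    for kind in sorted(rates):
        rate = rates[kind]
        if rate == 0:
            continue
        mode_s = 1.0 / rate
        t = edge_margin_s
        while True:
            wave, defl = render_ip_event(kind, preset, fs_hz, rng)
            dur = wave.size / fs_hz
            onset = t + float(_lognormal_intervals(rng, mode_s, interval_sigma, 1)[0])
            retries = 0
            while conflicts(onset, onset + dur):
                retries += 1
                if retries > max_retries:
                    raise PlacementError(
                        f"cannot place {kind} events at rate {rate}/s "
                        f"with {min_separation_s}s separation"
                    )
                onset += float(
                    _lognormal_intervals(rng, mode_s, interval_sigma, 1)[0]
                )
            end = onset + dur
            if end > duration_s - edge_margin_s:
                break
            _add(sig.samples, int(round(onset * fs_hz)), wave)
            rows.append((kind, sig.channel_id, onset, end, defl + onset))
            occupied.append((onset, end))
            t = onset
    rows.sort(key=lambda r: r[2])
    ann = AnnotationTable(
        pd.DataFrame(
            [(k, ch, s, e) for k, ch, s, e, _ in rows],
            columns=["label", "channel", "start_s", "end_s"],
        )
    )
    defl_map = {i: rows[i][4] for i in range(len(rows))}
    return sig, ann, defl_map


def macro_channel(
    micro: SampledSignal,
    attenuation: float = 0.25,
    smooth_cutoff_hz: float = 300.0,
    channel_id: str = "macro1",
) -> SampledSignal:
    """Macro-contact surrogate: an attenuated, low-passed copy of the micro
    signal. No volume-conduction physics — just the qualitative observation
    that nodule patterns appear smaller and smoother on adjacent macro
    contacts."""
    from scipy import signal as sps

    sos = sps.butter(4, smooth_cutoff_hz, btype="low", fs=micro.fs_hz,
                     output="sos")
    return SampledSignal(
        channel_id, micro.fs_hz,
        attenuation * sps.sosfiltfilt(sos, micro.samples), micro.t0_s,
    )


def generate_seizures(
    annotations: AnnotationTable,
    lfp: SampledSignal,
    n_seizures: int,
    seizure_dur_s: float = 30.0,
    gap_s: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> AnnotationTable:
    """Append seizure annotations (and an ictal LFP signature) to a recording.

    Seizures are placed on a regular grid starting after ``gap_s``,
    separated by at least ``gap_s``; the LFP gains a low-frequency ictal
    rhythm with superimposed fast activity for each seizure's duration.
    """
    rng = np.random.default_rng(seed)
    duration = lfp.duration_s
    spacing = (duration - 2 * gap_s) / max(n_seizures, 1)
    if spacing < seizure_dur_s + gap_s:
        raise PlacementError("recording too short for the requested seizures")
    rows = []
    for i in range(n_seizures):
        onset = gap_s + i * spacing + rng.uniform(0, 0.2 * gap_s)
        end = onset + seizure_dur_s
        n = int(round(seizure_dur_s * lfp.fs_hz))
        t = np.arange(n) / lfp.fs_hz
        env = np.hanning(n)
        rhythm = 60.0 * env * np.sin(2 * np.pi * 2.5 * t) + 15.0 * env * np.sin(
            2 * np.pi * 120.0 * t
        )
        _add(lfp.samples, int(round(onset * lfp.fs_hz)), rhythm)
        rows.append(("seizure", lfp.channel_id, onset, end))
    extra = AnnotationTable(
        pd.DataFrame(rows, columns=["label", "channel", "start_s", "end_s"])
    )
    return annotations.concat(extra)


# ---------------------------------------------------------------------------
# Unit gain profiles and spike trains
# ---------------------------------------------------------------------------

@dataclass
class GainCurve:
    """Multiplicative gain ``g(t)`` on a time axis relative to event onset.

    ``g`` is linearly interpolated inside ``[t[0], t[-1]]`` and 1 outside.
    """

    t: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("gain must be non-negative everywhere")

    def __call__(self, tau: np.ndarray) -> np.ndarray:
        return np.interp(tau, self.t, self.g, left=1.0, right=1.0)


def phasic_gain(peak: float = 20.0, sigma_s: float = 0.05,
                center_s: float = 0.0) -> GainCurve:
    """Brief multiplicative burst (epileptic-spike-like), up to ~20x.

    ``center_s`` places the burst relative to the annotated onset (the
    rendered spike transient peaks ~0.1 s after its annotation onset).
    """
    t = center_s + np.linspace(-4 * sigma_s, 4 * sigma_s, 201)
    g = 1 + (peak - 1) * np.exp(-((t - center_s) ** 2) / (2 * sigma_s**2))
    g[[0, -1]] = 1.0
    return GainCurve(t, g)


def sustained_gain(peak: float = 100.0, dur_s: float = 1.0,
                   ramp_s: float = 0.1) -> GainCurve:
    """Flat-top elevated gain over ``dur_s`` with cosine ramps (SD+F-like)."""
    tr = np.linspace(0, ramp_s, 25)
    up = 1 + (peak - 1) * 0.5 * (1 - np.cos(np.pi * tr / ramp_s))
    t = np.concatenate([tr, dur_s - ramp_s + tr])
    g = np.concatenate([up, up[::-1]])
    return GainCurve(t, g)


def periodic_gain(peak: float = 10.0, period_s: float = 0.5,
                  n_cycles: int = 4, sigma_s: float = 0.06,
                  offset_s: float = 0.175) -> GainCurve:
    """Gain bumps locked to the periodic deflection peaks (PD+F-like).

    ``offset_s`` is the lag of the first deflection peak after the annotated
    onset (half the rendered slow-lobe width).
    """
    t = np.arange(-0.2, (n_cycles - 1) * period_s + offset_s + 0.4, 0.005)
    g = np.ones_like(t)
    for k in range(n_cycles):
        g += (peak - 1) * np.exp(
            -((t - (k * period_s + offset_s)) ** 2) / (2 * sigma_s**2)
        )
    g[[0, -1]] = 1.0
    return GainCurve(t, g)


def inverse_gain(depth: float = 0.0, dur_s: float = 0.5,
                 start_s: float = 0.0) -> GainCurve:
    """Suppressed unit: gain dips to ``depth`` (< 1) during the event."""
    if not 0 <= depth <= 1:
        raise ValueError("inverse-gain depth must lie in [0, 1]")
    eps = 1e-9  # sharp edges: no interpolation ramp into the dip
    t = start_s + np.array([-eps, 0.0, dur_s, dur_s + eps])
    g = np.array([1.0, depth, depth, 1.0])
    return GainCurve(t, g)


@dataclass
class UnitGainProfile:
    """How one unit's rate is gain-modulated around each pattern."""

    unit_id: str
    baseline_rate_hz: float
    gains: dict[str, GainCurve] = field(default_factory=dict)  # kind -> curve
    inverse: bool = False
    ictal_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be positive")
        if self.inverse:
            for kind, curve in self.gains.items():
                if curve.g.min() >= 1 or curve.g.max() > 1:
                    raise ValueError(
                        f"inverse unit requires min g < 1 and max g <= 1 ({kind})"
                    )


def rate_on_grid(
    annotations: AnnotationTable,
    profile: UnitGainProfile,
    duration_s: float,
    grid_hz: float = 1000.0,
) -> np.ndarray:
    """lambda(t) on a regular grid: baseline times the product of event gains."""
    n = int(round(duration_s * grid_hz))
    lam = np.full(n, profile.baseline_rate_hz)
    tgrid = np.arange(n) / grid_hz
    for _, row in annotations.df.iterrows():
        if row["label"] == "seizure":
            if profile.ictal_gain != 1.0:
                mask = (tgrid >= row["start_s"]) & (tgrid < row["end_s"])
                lam[mask] *= profile.ictal_gain
            continue
        curve = profile.gains.get(row["label"])
        if curve is None:
            continue
        lo = row["start_s"] + curve.t[0]
        hi = row["start_s"] + curve.t[-1]
        i0 = max(int(np.floor(lo * grid_hz)), 0)
        i1 = min(int(np.ceil(hi * grid_hz)) + 1, n)
        if i1 > i0:
            lam[i0:i1] *= curve(tgrid[i0:i1] - row["start_s"])
    return lam


def generate_unit_spikes(
    annotations: AnnotationTable,
    profile: UnitGainProfile,
    duration_s: float,
    seed: int | np.random.Generator = 0,
    grid_hz: float = 1000.0,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times by thinning.

    Candidates are drawn homogeneously at ``max(lambda)`` and kept with
    probability ``lambda(t)/max(lambda)``; ties on the 1 ms lookup grid are
    broken by the exact candidate time, so output times are strictly
    increasing.
    """
    rng = np.random.default_rng(seed)
    lam = rate_on_grid(annotations, profile, duration_s, grid_hz)
    if lam.max() == 0:
        return np.array([])
    # thin chunk-by-chunk against the local rate bound, so a brief extreme
    # gain does not inflate the candidate count for the whole recording
    chunk_s = 1.0
    chunk_n = int(round(chunk_s * grid_hz))
    times = []
    for i0 in range(0, lam.size, chunk_n):
        seg = lam[i0 : i0 + chunk_n]
        lam_max = float(seg.max())
        if lam_max == 0:
            continue
        t_lo = i0 / grid_hz
        t_hi = min((i0 + seg.size) / grid_hz, duration_s)
        n_cand = rng.poisson(lam_max * (t_hi - t_lo))
        cand = np.sort(rng.uniform(t_lo, t_hi, size=n_cand))
        idx = np.minimum((cand * grid_hz).astype(int) - i0, seg.size - 1)
        keep = rng.uniform(0, 1, size=n_cand) < seg[idx] / lam_max
        times.append(cand[keep])
    return np.unique(np.concatenate(times)) if times else np.array([])


#: Time of the rendered spike-transient peak after its annotated onset (the
#: difference-of-Gaussians segment starts 1.5 durations before its peak).
ES_PEAK_OFFSET_S = 0.105


def default_unit_profiles(
    preset: NodulePreset | None = None,
) -> list[UnitGainProfile]:
    """The four archetype units: phasic, sustained, periodic, inverse.

    Gain supports scale with the preset's event morphology (train length,
    slow-wave duration) so that firing-rate modulation tracks the LFP shape
    for every nodule, as recorded units do.
    """
    if preset is None:
        preset = NODULE_PRESETS[1]
    train_s = (preset.pdf_n_deflections - 1) * preset.pdf_period_s + 0.35
    sdf_s = preset.sdf_slow_dur_s or 1.0
    return [
        UnitGainProfile(
            "u1_phasic", 10.0,
            {"ES": phasic_gain(20.0, 0.03, ES_PEAK_OFFSET_S),
             "SD+F": phasic_gain(8.0, 0.15, sdf_s / 2),
             "PD+F": phasic_gain(6.0, 0.15, 0.25)},
            ictal_gain=3.0,
        ),
        UnitGainProfile(
            "u2_sustained", 10.0,
            {"SD+F": sustained_gain(100.0, sdf_s),
             "ES": phasic_gain(10.0, 0.03, ES_PEAK_OFFSET_S),
             "PD+F": sustained_gain(5.0, train_s)},
            ictal_gain=3.0,
        ),
        UnitGainProfile(
            "u3_periodic", 10.0,
            {"PD+F": periodic_gain(10.0, preset.pdf_period_s,
                                   preset.pdf_n_deflections,
                                   offset_s=min(0.35, 0.7 * preset.pdf_period_s) / 2),
             "ES": phasic_gain(15.0, 0.03, ES_PEAK_OFFSET_S),
             "SD+F": sustained_gain(20.0, sdf_s)},
            ictal_gain=2.0,
        ),
        UnitGainProfile(
            "u4_inverse", 10.0,
            {"PD+F": inverse_gain(0.0, train_s + 0.2, -0.1),
             "SD+F": inverse_gain(0.0, sdf_s, -0.05),
             "ES": inverse_gain(0.0, 0.3, ES_PEAK_OFFSET_S - 0.15)},
            inverse=True,
            ictal_gain=1.0,
        ),
    ]


def synthesize_recording(
    nodule_id: int = 1,
    duration_s: float = 600.0,
    fs_hz: float = 1000.0,
    seed: int = 0,
    rates: dict[str, float] | None = None,
    profiles: list[UnitGainProfile] | None = None,
    n_seizures: int = 0,
) -> SynthRecording:
    """One-call scenario: LFP + annotations + archetype unit spike trains."""
    preset = NODULE_PRESETS[nodule_id]
    rng = np.random.default_rng(seed)
    sig, ann, defl = generate_ip_series(
        preset, duration_s, fs_hz, rates, seed=rng
    )
    if n_seizures:
        ann = generate_seizures(ann, sig, n_seizures, seed=rng)
    if profiles is None:
        profiles = default_unit_profiles(preset)
    spikes = {
        p.unit_id: generate_unit_spikes(ann, p, duration_s, seed=rng)
        for p in profiles
    }
    return SynthRecording(
        lfp=sig,
        annotations=ann,
        spikes=spikes,
        profiles={p.unit_id: p for p in profiles},
        deflections=defl,
        seed=seed,
    )
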