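"""End-to-end orchestration: synthesis / loading -> alignment -> spectra,
periodicity, unit metrics, peri-event statistics -> report tables and figures.

Defaults follow the analysis conventions of the recordings this pipeline
emulates: 200 ms (epileptic spikes) / 400 ms Hanning windows in 5 ms steps
over 60-200 Hz, percentage change against a -1..-0.5 s (ES) or -2..-1 s
baseline, 10 / 50 ms rate kernels at 1000 Hz, 100 statistics bins, and
cluster permutation at first-level p < 0.01 with cluster p < 0.05 over
10,000 sign flips.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import align_trials, epoch
from .cluster import ALPHA_CLUSTER, ALPHA_FIRST, N_PERM, cluster_permutation_test
from .io import AnnotationTable, SampledSignal
from .perievent import (
    UnitIPStats,
    baseline_bins,
    bin_rates,
    kernel_rate,
    modulation_percent,
    rate_lfp_correlation,
    seizure_raster,
    sig_windows,
)
from .periodicity import interval_mode, periodicity_fraction
from .spectral import baseline_normalize, compute_tfr, peak_frequency
from .synth import IP_KINDS, SynthRecording, synthesize_recording
from .units import baseline_stats, rpv


@dataclass(frozen=True)
class PatternParams:
    """Per-pattern analysis windows; all times relative to the event onset."""

    epoch_window_s: tuple[float, float]
    baseline_window_s: tuple[float, float]
    tfr_window_s: float
    kernel_sigma_s: float
    max_lag_s: float


#: Epileptic spikes are brief: a tighter epoch, 200 ms window, 10 ms kernel.
#: The slower patterns use the wide epoch, 400 ms window, 50 ms kernel.
PATTERN_PARAMS: dict[str, PatternParams] = {
    "ES": PatternParams((-1.5, 1.5), (-1.0, -0.5), 0.2, 0.010, 0.15),
    "PD+F": PatternParams((-3.0, 3.0), (-2.0, -1.0), 0.4, 0.050, 0.30),
    "SD+F": PatternParams((-3.0, 3.0), (-2.0, -1.0), 0.4, 0.050, 0.30),
    "PF": PatternParams((-3.0, 3.0), (-2.0, -1.0), 0.4, 0.050, 0.30),
}


@dataclass
class RunConfig:
    """Everything a run needs; defaults are the standard analysis parameters."""

    out_dir: str = "results/run"
    seed: int = 0
    # synthesis scenario (used when no input paths are given)
    nodule_id: int = 1
    duration_s: float = 900.0
    fs_hz: float = 1000.0
    n_seizures: int = 0
    rates: dict | None = None
    # input paths (optional; override synthesis)
    signal_path: str | None = None
    signal_format: str = "raw"
    annotations_path: str | None = None
    spikes_path: str | None = None
    # statistics
    alpha_first: float = ALPHA_FIRST
    alpha_cluster: float = ALPHA_CLUSTER
    n_perm: int = N_PERM
    n_bins: int = 100
    min_events: int = 5
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _load_or_synthesize(config: RunConfig) -> SynthRecording:
    from . import io as _io

    if config.signal_path is not None:
        signals = _io.read_signal(config.signal_path, config.signal_format)
        ann = (
            _io.read_annotations(config.annotations_path)
            if config.annotations_path
            else AnnotationTable()
        )
        spikes = (
            _io.read_spike_times(config.spikes_path) if config.spikes_path else {}
        )
        return SynthRecording(lfp=signals[0], annotations=ann, spikes=spikes)
    return synthesize_recording(
        nodule_id=config.nodule_id,
        duration_s=config.duration_s,
        fs_hz=config.fs_hz,
        seed=config.seed,
        rates=config.rates,
        n_seizures=config.n_seizures,
    )


def analyze_pattern(
    lfp: SampledSignal,
    annotations: AnnotationTable,
    label: str,
    align: bool = True,
):
    """Epoch + align + baseline-normalized TFR for one pattern.

    Returns ``(trial_matrix, tfr_pct)`` or ``(None, None)`` when no usable
    events exist.
    """
    p = PATTERN_PARAMS[label]
    tm = epoch(lfp, annotations, label, p.epoch_window_s, pad_s=p.max_lag_s)
    if tm.n_trials == 0:
        return None, None
    if align and tm.n_trials >= 2:
        tm = align_trials(tm, max_lag_s=p.max_lag_s)
    tfr = compute_tfr(tm, p.tfr_window_s)
    tfr_pct = baseline_normalize(tfr, p.baseline_window_s)
    return tm, tfr_pct


def pattern_peak(tfr_pct, label: str) -> tuple[float, float]:
    """Peak frequency of the event window (onset to +1 s; ES: +-0.2 s)."""
    win = (-0.2, 0.2) if label == "ES" else (0.0, 1.0)
    return peak_frequency(tfr_pct, win)


def event_table(annotations: AnnotationTable, deflections: dict,
                hours: float) -> pd.DataFrame:
    """Descriptive per-pattern statistics: t (h), n, lambda, mean/SD interval,
    periodicity percentage over the deflection ground truth."""
    rows = []
    df = annotations.df
    for label in [k for k in IP_KINDS if (df["label"] == k).any()]:
        onsets = df.loc[df["label"] == label, "start_s"].to_numpy()
        stats_ = interval_mode(onsets) if onsets.size >= 2 else None
        # pool per-event deflection trains (PD+F has >= 3 deflections each)
        fracs = []
        conforming = total = 0
        for i, d in deflections.items():
            if df.loc[i, "label"] == label and len(d) >= 3:
                rep = periodicity_fraction(d)
                conforming += rep.n_conforming
                total += rep.n_intervals
                fracs.append(rep.mean_period_s)
        rows.append(
            {
                "pattern": label,
                "t_h": hours,
                "n": int(onsets.size),
                "lambda_s": stats_.lambda_mode_s if stats_ else np.nan,
                "mean_interval_s": stats_.mean_interval_s if stats_ else np.nan,
                "sd_interval_s": stats_.sd_interval_s if stats_ else np.nan,
                "mean_period_s": float(np.mean(fracs)) if fracs else np.nan,
                "periodicity_pct": (
                    int(np.floor(100 * conforming / total + 0.5)) if total else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def analyze_unit_pattern(
    spike_times: np.ndarray,
    tm,
    avg_lfp: np.ndarray,
    unit_id: str,
    label: str,
    config: RunConfig,
) -> tuple[UnitIPStats, "object"]:
    """Kernel rate -> 100 bins -> cluster permutation -> modulation summary."""
    p = PATTERN_PARAMS[label]
    per = kernel_rate(
        spike_times, tm.onsets_s, p.epoch_window_s, p.kernel_sigma_s,
        unit_id=unit_id, label=label,
    )
    binned = bin_rates(per, config.n_bins)
    base_idx = baseline_bins(per.bin_centers, p.baseline_window_s)
    result = cluster_permutation_test(
        binned,
        binned[:, base_idx],
        alpha_first=config.alpha_first,
        alpha_cluster=config.alpha_cluster,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    up, down = modulation_percent(per, result, p.baseline_window_s)
    # correlate the continuous (1 ms) average rate with the average LFP
    rho, status = rate_lfp_correlation(per.avg_rate, avg_lfp)
    width = float(per.bin_centers[1] - per.bin_centers[0])
    return UnitIPStats(
        unit_id=unit_id,
        label=label,
        up_pct=up,
        down_pct=down,
        rho=rho,
        rho_status=status,
        sig_windows=sig_windows(result, per.bin_centers, width),
        baseline_fr_hz=float(
            binned.mean(axis=0)[base_idx].mean()
        ),
    ), per


def run_ip_analysis(config: RunConfig) -> dict:
    """Full interictal analysis; writes report tables, figures and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _load_or_synthesize(config)
    hours = rec.lfp.duration_s / 3600.0

    table3 = event_table(rec.annotations, rec.deflections, hours)
    table3.to_csv(out / "pattern_summary.tsv", sep="\t", index=False)

    unit_rows = []
    problems = []
    tms, tfrs = {}, {}
    for label in IP_KINDS:
        n_events = int((rec.annotations.df["label"] == label).sum())
        if n_events < config.min_events:
            if n_events:
                problems.append(f"{label}: only {n_events} events, skipped")
            continue
        tm, tfr_pct = analyze_pattern(rec.lfp, rec.annotations, label)
        if tm is None:
            problems.append(f"{label}: no usable epochs")
            continue
        tms[label], tfrs[label] = tm, tfr_pct
        if config.make_figures:
            _tfr_figure(tfr_pct, out / f"tfr_{label.replace('+', '')}.svg")

    peak_rows = [
        {"pattern": lab, "f_peak_hz": pattern_peak(tfr, lab)[0],
         "peak_pct": pattern_peak(tfr, lab)[1], "n_trials": tms[lab].n_trials}
        for lab, tfr in tfrs.items()
    ]
    pd.DataFrame(peak_rows).to_csv(out / "tfr_peaks.tsv", sep="\t", index=False)

    for uid, spikes in rec.spikes.items():
        row = {"unit_id": uid}
        if spikes.size >= 2:
            row["rpv_pct"] = rpv(spikes)
        bs = baseline_stats(spikes, rec.annotations, rec.lfp.duration_s)
        row["fr_hz"], row["cv2"] = bs.fr_hz, bs.cv2
        for label, tm in tms.items():
            ustats, per = analyze_unit_pattern(
                spikes, tm, tm.average(), uid, label, config
            )
            short = label.replace("+", "")
            row[f"{short}_up_pct"] = "n.s." if ustats.up_pct is None else round(ustats.up_pct)
            row[f"{short}_down_pct"] = "n.s." if ustats.down_pct is None else round(ustats.down_pct)
            row[f"{short}_rho"] = round(ustats.rho, 2) if ustats.rho_status == "ok" else "n.s."
            row[f"{short}_sig_windows"] = ";".join(
                f"{a:.2f}:{b:.2f}" for a, b in ustats.sig_windows
            )
            if config.make_figures:
                _psth_figure(per, tm, out / f"psth_{uid}_{short}.svg")
        unit_rows.append(row)
    table4 = pd.DataFrame(unit_rows)
    table4.to_csv(out / "unit_summary.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "n_annotations": len(rec.annotations),
        "problems": problems,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "pattern_summary": table3,
        "unit_summary": table4,
        "tfr_peaks": pd.DataFrame(peak_rows),
        "problems": problems,
        "out_dir": out,
    }


PRESET_FREQ_FIELDS = {"PD+F": "pdf_fast_hz", "SD+F": "sdf_fast_hz",
                      "ES": "es_fast_hz"}


def recover_peak_frequency(
    nodule_id: int,
    kind: str,
    n_events: int = 100,
    seed: int = 0,
    fs_hz: float = 1000.0,
) -> dict:
    """Generate a single-pattern series and recover its fast-activity peak.

    Synthesizes ``n_events`` events of ``kind`` with the given nodule preset,
    epochs and aligns them, computes the baseline-normalized TFR and returns
    the peak frequency together with the generator's ground truth and the
    frequency-bin width.
    """
    from .synth import NODULE_PRESETS, generate_ip_series

    preset = NODULE_PRESETS[nodule_id]
    expected = getattr(preset, PRESET_FREQ_FIELDS[kind])
    if expected is None:
        raise ValueError(f"nodule {nodule_id} has no {kind} parameters")
    rate = 1.0 / 10.0
    # budget enough recording for ~n_events despite the no-overlap/minimum
    # separation constraints (PD+F trains span several seconds)
    if kind == "PD+F":
        span = (preset.pdf_n_deflections - 1) * preset.pdf_period_s + 0.5
    elif kind == "SD+F":
        span = (preset.sdf_slow_dur_s or 0.0) + 0.2
    else:
        span = 0.4
    duration = n_events * (1.0 / rate + span + 5.0) + 60.0
    sig, ann, _ = generate_ip_series(
        preset, duration, fs_hz, {kind: rate}, seed=seed
    )
    tm, tfr_pct = analyze_pattern(sig, ann, kind)
    f_peak, peak_pct = pattern_peak(tfr_pct, kind)
    return {
        "f_peak_hz": f_peak,
        "expected_hz": float(expected),
        "bin_hz": tfr_pct.freq_resolution_hz,
        "peak_pct": peak_pct,
        "n_trials": tm.n_trials,
    }


def run_seizure_analysis(config: RunConfig) -> dict:
    """Seizure-locked rasters and descriptive pre/post rates; no p-values."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _load_or_synthesize(config)
    onsets = rec.annotations.select("seizure")["start_s"].to_numpy()
    if onsets.size == 0:
        (out / "seizure_summary.tsv").write_text("status\tno seizures\n")
        return {"rasters": {}, "summary": None, "status": "no seizures"}
    rasters = seizure_raster(rec.spikes, onsets)
    rows = [
        {
            "unit_id": uid,
            "n_seizures": len(r.trials),
            "pre_rate_hz": r.pre_rate_hz,
            "post_rate_hz": r.post_rate_hz,
            "ratio": r.ratio,
        }
        for uid, r in rasters.items()
    ]
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "seizure_summary.tsv", sep="\t", index=False)
    if config.make_figures:
        _raster_figure(rasters, out / "seizure_rasters.svg")
    return {"rasters": rasters, "summary": summary, "status": "ok"}


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _tfr_figure(tfr, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax, axin) = plt.subplots(
        1, 2, figsize=(8, 3), gridspec_kw={"width_ratios": [3, 1]}
    )
    extent = [tfr.times_s[0], tfr.times_s[-1], tfr.freqs_hz[0], tfr.freqs_hz[-1]]
    im = ax.imshow(tfr.power, aspect="auto", origin="lower", extent=extent,
                   cmap="RdBu_r")
    ax.set(xlabel="time (s)", ylabel="frequency (Hz)", title=tfr.label)
    fig.colorbar(im, ax=ax, label="% change")
    f, v = tfr.freqs_hz, tfr.power.mean(axis=1)
    win = (-0.2, 0.2) if tfr.label == "ES" else (0.0, 1.0)
    mask = (tfr.times_s >= win[0]) & (tfr.times_s <= win[1])
    spec = tfr.power[:, mask].mean(axis=1)
    axin.plot(f, spec)
    axin.axvline(f[int(np.argmax(spec))], ls=":", color="k")
    axin.set(xlabel="Hz", ylabel="% change")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _psth_figure(per, tm, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 4), sharex=True)
    ax1.plot(per.times, per.avg_rate, lw=1)
    ax1.set(ylabel="rate (spk/s)", title=f"{per.unit_id} {per.label}")
    ax1b = ax1.twinx()
    ax1b.plot(tm.times, tm.average(), color="gray", alpha=0.5, lw=0.8)
    ax1b.set_ylabel("LFP (uV)")
    ax2.imshow(per.rate[:60], aspect="auto", origin="lower",
               extent=[per.times[0], per.times[-1], 0, min(60, per.rate.shape[0])],
               cmap="Greys")
    ax2.set(xlabel="time (s)", ylabel="trial")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _raster_figure(rasters, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        len(rasters), 1, figsize=(7, 1.6 * len(rasters)), sharex=True, squeeze=False
    )
    for ax, (uid, r) in zip(axes[:, 0], rasters.items()):
        for i, row in enumerate(r.trials):
            ax.vlines(row, i + 0.1, i + 0.9, lw=0.4, color="k")
        ax.axvline(0, color="r", lw=0.8)
        ax.set_ylabel(uid, fontsize=7)
    axes[-1, 0].set_xlabel("time from seizure onset (s)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
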