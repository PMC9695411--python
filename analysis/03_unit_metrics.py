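#!/usr/bin/env python
"""Per-unit quality and resting-state metrics.

Two parts. First, a detection check on a short 32 kHz segment: spikes of
known times injected into noise must be recovered by MAD thresholding of the
>300 Hz high-passed trace. Second, for every simulated unit: refractory
violations (ISI < 2 ms), SUA/MUA call, and baseline firing rate / CV2 over
10-s windows that avoid all annotated events.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pnhmicro import (
    SampledSignal,
    baseline_stats,
    classify_unit,
    detect_spikes,
    read_annotations,
    read_signal,
    read_spike_times,
    rpv,
)

SIM = Path("results/sim")
OUT = Path("results/units")


def detection_check(seed: int = 3) -> None:
    rng = np.random.default_rng(seed)
    fs, dur, n_spk = 32000, 20.0, 100
    x = rng.standard_normal(int(dur * fs))
    sigma = np.median(np.abs(x - np.median(x))) / 0.6745
    t = np.arange(-20, 21) / fs
    wave = -8 * sigma * np.exp(-(t**2) / (2 * 0.00015**2))
    truth = 1.0 + (dur - 2.0) * (np.arange(n_spk) + 0.5) / n_spk
    for t0 in truth:
        i = int(round(t0 * fs))
        x[i - 20 : i + 21] += wave
    times, amps = detect_spikes(SampledSignal("m", float(fs), x), k_mad=6.0)
    hits = sum(np.min(np.abs(times - t0)) <= 0.0005 for t0 in truth)
    print(f"detection: {hits}/{n_spk} injected spikes recovered, "
          f"{len(times) - hits} extra events, "
          f"mean amplitude {amps.mean():.1f} (robust-SD units x sigma)")


def main() -> None:
    if not SIM.exists():
        print("run analysis/01_simulate_recordings.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    detection_check()

    rows = []
    for nodule in (1, 2, 3, 4):
        d = SIM / f"nodule{nodule}"
        ann = read_annotations(d / "annotations.tsv")
        trains = read_spike_times(d / "spikes.tsv")
        (lfp,) = read_signal(d / "lfp.bin", "raw")
        duration = lfp.duration_s
        for uid, times in trains.items():
            r = rpv(times)
            # synthetic trains carry no waveforms; assume clean amplitudes so
            # the class call reflects the refractory criterion alone
            cls = classify_unit(r, amplitude_snr=8.0)
            bs = baseline_stats(times, ann, duration)
            rows.append({
                "nodule": nodule, "unit_id": uid, "rpv_pct": round(r, 2),
                "class": cls, "fr_hz": round(bs.fr_hz, 2),
                "cv2": round(bs.cv2, 3), "n_windows": bs.n_windows,
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "unit_quality.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nnote: archetype units share a 10 Hz baseline; CV2 near 1 "
          f"confirms Poisson-like resting statistics. Table under {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
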