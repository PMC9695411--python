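#!/usr/bin/env python
"""Seizure-locked unit activity: rasters and pre/post rates, no p-values.

Spike trains are time-locked to every annotated seizure onset of the two
seizure-bearing simulated nodules (6 + 6 seizures). With so few seizures no
inferential statistics are computed — the rasters and the pre/post rate
ratio per unit are the deliverable. Units with an ictal gain should elevate
their rate at onset; the inverse archetype (ictal gain 1) should not.
"""

import sys
from pathlib import Path

import pandas as pd

from pnhmicro import read_annotations, read_spike_times, seizure_raster
from pnhmicro.pipeline import _raster_figure

SIM = Path("results/sim")
OUT = Path("results/seizures")


def main() -> None:
    if not SIM.exists():
        print("run analysis/01_simulate_recordings.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    rows, total = [], 0
    for nodule in (1, 4):
        d = SIM / f"nodule{nodule}"
        ann = read_annotations(d / "annotations.tsv")
        onsets = ann.select("seizure")["start_s"].to_numpy()
        if onsets.size == 0:
            continue
        total += onsets.size
        trains = read_spike_times(d / "spikes.tsv")
        rasters = seizure_raster(trains, onsets, window_s=(-30.0, 30.0))
        _raster_figure(rasters, OUT / f"rasters_nodule{nodule}.svg")
        for uid, r in rasters.items():
            rows.append({
                "nodule": nodule, "unit_id": uid, "n_seizures": len(r.trials),
                "pre_rate_hz": round(r.pre_rate_hz, 2),
                "post_rate_hz": round(r.post_rate_hz, 2),
                "ratio": round(r.ratio, 2),
            })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "seizure_rates.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\n{total} seizures raster-locked across nodules 1 and 4; "
          f"figures and table under {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
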