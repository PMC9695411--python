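#!/usr/bin/env python
"""Simulate one surrogate micro-LFP recording per nodule preset.

Each recording carries the nodule's three interictal patterns (nodule 3 has
no sporadic-discharge pattern), the four archetype units, and — for nodules
1 and 4 — six seizures each, matching the seizure counts available for
unit-level analysis. Signals go out as raw float32 + JSON sidecar,
annotations and spike times as TSV, so every later stage runs from files.
"""

import sys
from pathlib import Path

import pandas as pd

from pnhmicro import (
    synthesize_recording,
    write_annotations,
    write_raw,
    write_spike_times,
)

OUT = Path("results/sim")
SEED = 11
DURATION_S = {1: 1800.0, 2: 1200.0, 3: 1200.0, 4: 1800.0}
N_SEIZURES = {1: 6, 2: 0, 3: 0, 4: 6}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for nodule in (1, 2, 3, 4):
        rec = synthesize_recording(
            nodule_id=nodule,
            duration_s=DURATION_S[nodule],
            seed=SEED + nodule,
            n_seizures=N_SEIZURES[nodule],
        )
        d = OUT / f"nodule{nodule}"
        d.mkdir(exist_ok=True)
        write_raw([rec.lfp], d / "lfp.bin")
        write_annotations(rec.annotations, d / "annotations.tsv")
        write_spike_times(rec.spikes, d / "spikes.tsv")
        pd.DataFrame(
            [(i, t) for i, times in rec.deflections.items() for t in times],
            columns=["event_index", "time_s"],
        ).to_csv(d / "deflections.tsv", sep="\t", index=False)
        counts = rec.annotations.df["label"].value_counts().to_dict()
        print(f"nodule {nodule}: {DURATION_S[nodule]/60:.0f} min, "
              f"events {counts}, units {len(rec.spikes)}")
    print(f"recordings under {OUT}/")


if __name__ == "__main__":
    sys.exit(main())
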