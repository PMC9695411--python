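# pnhmicro

Analysis pipeline for interictal epileptic patterns and single-unit firing in
intracranial **microelectrode** recordings of periventricular nodular
heterotopia (PNH) — ectopic gray-matter nodules that are a frequent cause of
drug-resistant epilepsy. Microwires implanted inside a nodule record both the
local field potential (LFP) and extracellular action potentials, which makes
it possible to ask how ectopic neurons behave during the nodule's own
epileptiform discharges and during seizures.

The pipeline covers, end to end:

- **Synthetic recordings with ground truth** (`pnhmicro.synth`): 1/f
  background plus the three interictal pattern (IP) classes seen in nodules —
  periodic discharges plus fast activity (PD+F: ≥ 3 periodic slow waves, each
  with a narrow-band 60–200 Hz burst), sporadic discharges plus fast activity
  (SD+F: a single 0.5–4 s slow wave with a prolonged burst), and epileptic
  spikes (ES: sharp 50–100 ms transients with a burst) — along with
  inhomogeneous-Poisson unit spike trains whose rate is gain-modulated around
  each event, λ(t) = λ₀ · Π g(t − onsetₖ), and seizure epochs with sustained
  rate elevation. Per-nodule presets carry the narrow-band frequencies
  92/135/106/81 Hz (PD+F), 102/134/121/97 Hz (ES) and 96/111/–/77 Hz (SD+F).
- **I/O and rate conversion** (`pnhmicro.io`): EDF and raw-float32+sidecar
  signals, TSV annotations and spike times, zero-phase anti-aliased
  downsampling to the common 1 kHz analysis rate.
- **Event alignment** (`pnhmicro.alignment`): epoching around annotated
  onsets and iterative cross-correlation alignment to the grand average.
- **Time–frequency analysis** (`pnhmicro.spectral`): Hanning-taper power in
  5 ms steps (200 ms windows for ES, 400 ms otherwise), percentage change
  against pre-event baselines (−1…−0.5 s for ES, −2…−1 s otherwise),
  60–200 Hz band averages and peak-frequency extraction.
- **Periodicity** (`pnhmicro.periodicity`): fraction of inter-deflection
  intervals deviating < 25 % from the train's mean period, and the mode λ of
  inter-event intervals.
- **Unit metrics** (`pnhmicro.units`): MAD-threshold spike detection on
  > 300 Hz high-passed data, refractory-period violations (ISI < 2 ms),
  SUA/MUA classification, and baseline firing rate / CV2 over 10-s windows
  free of annotated events.
- **Peri-event statistics** (`pnhmicro.perievent`, `pnhmicro.cluster`):
  Gaussian-kernel firing rates at 1000 Hz (σ = 10 ms for ES, 50 ms
  otherwise), 100-bin trial matrices, rate–LFP correlation ρ, maximal
  significant modulation (↑ %, ↓ %), and a sign-flip **cluster-based
  permutation test** against baseline (first-level p < 0.01, cluster
  p < 0.05, 10 000 permutations by default).
- **Seizure-locked rasters** (`pnhmicro.perievent.seizure_raster`):
  descriptive pre/post rates only — no inferential statistics on the handful
  of seizures.

## Worked example

```python
from pnhmicro import synthesize_recording
from pnhmicro.pipeline import RunConfig, analyze_pattern, analyze_unit_pattern, pattern_peak

rec = synthesize_recording(nodule_id=1, duration_s=1200, seed=11)
tm, tfr = analyze_pattern(rec.lfp, rec.annotations, "ES")
f_peak, pct = pattern_peak(tfr, "ES")
print(f"{tm.n_trials} epileptic spikes, fast activity peak {f_peak:.0f} Hz "
      f"(+{pct:.0f}% vs baseline)")

cfg = RunConfig(n_perm=1000, seed=11)
st, per = analyze_unit_pattern(rec.spikes["u1_phasic"], tm, tm.average(),
                               "u1_phasic", "ES", cfg)
print(f"u1_phasic: up {st.up_pct:.0f}%, rho {st.rho:.2f}")
```

prints

```
42 epileptic spikes, fast activity peak 105 Hz (+2407% vs baseline)
u1_phasic: up 1650%, rho 0.44
```

i.e. the 102 Hz burst frequency of the nodule-1 preset is recovered within
one 5 Hz frequency bin, and the phasic archetype unit (20× gain at the spike
transient) shows a large, significant, positive-correlated rate increase.

The numbered drivers under `analysis/` run the same stages as a narrative
study over all four nodule presets (simulate → pattern characterization →
unit quality → peri-event statistics → seizure rasters), writing their
tables and figures under `results/`:

```bash
python analysis/01_simulate_recordings.py
python analysis/02_characterize_patterns.py
python analysis/03_unit_metrics.py
python analysis/04_perievent_statistics.py
python analysis/05_seizure_rasters.py
```

A thin CLI wraps the same pipeline: `pnhmicro synth --seed 1 --out dir`,
`pnhmicro analyze --out dir`, `pnhmicro seizures --out dir`.

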