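# Methods

## What the pipeline computes

Microelectrode recordings inside heterotopic nodules show three recurring
interictal patterns (IPs): trains of periodic slow waves with superimposed
narrow-band fast activity (PD+F), isolated slow waves with prolonged fast
activity (SD+F), and brief epileptic spikes (ES). The pipeline characterizes
these patterns in the time–frequency domain, quantifies the periodicity of
the periodic trains, and tests whether each sorted unit's firing rate is
modulated around each pattern; seizure-locked firing is described without
inference. All analysis runs on a common 1 kHz timeline in microvolts,
seconds from recording start, with half-open annotation intervals
`[start, end)`. Any window overlapping an `artifact` annotation is excluded
everywhere.

## Synthetic recordings (what they emulate, and what they don't)

Because depth-microelectrode recordings of this kind are not publicly
depositable, every stage is validated against a generator with known ground
truth.

- **Background**: Gaussian noise with power spectral density ∝ 1/f^a
  (default a = 1, RMS 10 µV), synthesized by spectral shaping. Nodule
  backgrounds are low-amplitude, which this mimics only in spirit.
- **Waveforms**: slow deflections are raised-cosine lobes (amplitude 90 µV);
  the ES transient is a difference of Gaussians (σ = 14/35 ms, undershoot
  coefficient 0.35, net-positive area); fast activity is a Hanning-enveloped
  sinusoid (25 µV) at the preset frequency — one ~0.15 s burst per PD+F
  deflection, one 0.5–1.5 s burst per SD+F wave, one 0.1 s burst per ES.
  These shapes are smooth and band-limited, so an event's only narrow-band
  60–200 Hz content is its burst: the preset frequency is an unambiguous
  spectral ground truth. Per-nodule presets carry the observed narrow-band
  peaks (PD+F 92/135/106/81 Hz; ES 102/134/121/97 Hz; SD+F 96/111/77 Hz,
  with nodule 3 lacking the SD+F pattern) and mean intra-train periods of
  0.511/0.574/1.074/1.0 s (the 1.0 s value is a rounded placeholder where
  the candidate reading was ambiguous). Intra-train period jitter is
  multiplicative Gaussian with SD 15 % of the period.
- **Event placement**: inter-event intervals are log-normal (σ = 0.5) with
  mode 1/rate — strictly positive and unimodal, mimicking the heavy-tailed
  gap between the modal and mean inter-event interval seen in long
  recordings. Same-kind events never overlap, and any two events keep a
  5 s minimum separation so that pre-event baselines are not contaminated
  by neighboring high-gain events. Default per-pattern rate: one event per
  20 s (analysis-sized recordings need ~20–100 events per pattern, not the
  thousands a full day yields).
- **Units**: spike times are an inhomogeneous Poisson process sampled by
  thinning against a per-second local rate bound,
  λ(t) = λ₀ · Π g(t − onsetₖ), with four gain archetypes at λ₀ = 10 Hz:
  phasic (20× Gaussian bump at the ES transient), sustained (100× flat-top
  over the SD+F slow wave), periodic (10× bumps at each PD+F deflection),
  and inverse (gain 0 during events — full suppression). Gain supports scale
  with the preset's event morphology so rate modulation tracks the LFP
  shape, as recorded units do. Seizures multiply the rate by a sustained
  ictal gain (default 2–3× for the excitable archetypes, 1× for the
  inverse unit).
- **Determinism**: every stochastic step draws from one
  `numpy.random.Generator`; identical (config, seed) is bit-identical.

Passing tests on these surrogates show the *machinery* recovers known
modulation, spectra and statistics at realistic SNR; they cannot show
robustness to waveform nonstationarity, electrode drift, cell bursting
(non-Poisson ISI), or volume-conducted cortical activity, none of which the
generator models.

## Analysis parameters (defaults and why)

| Stage | Parameter | ES | other patterns |
|---|---|---|---|
| Epoch | window | −1.5…+1.5 s | −3…+3 s |
| Baseline | window | −1…−0.5 s | −2…−1 s |
| TFR | Hanning window / step | 200 ms / 5 ms | 400 ms / 5 ms |
| TFR | frequency grid | 5 Hz bins, 60–200 Hz | 2.5 Hz bins, 60–200 Hz |
| Rate | Gaussian kernel σ | 10 ms | 50 ms |
| Statistics | bins per trial | 100 (30 ms) | 100 (60 ms) |
| Alignment | max lag | 150 ms | 300 ms |

The frequency grid uses the exact DFT bins of the taper window (multiples of
1/window), so no interpolation enters peak-frequency estimates; peak ties
resolve to the lowest frequency. TFR power is averaged across trials before
baseline normalization, 100·(P−B)/B (the per-trial variant is a flag).
Windows extending past an epoch are dropped, never padded.

**Alignment** iterates: template = current grand average; each trial moves to
the integer lag (within the bound) maximizing its Pearson correlation
(mean-subtracted) with the template; ties resolve to the smallest |lag|;
stops when no shift changes by more than one sample (max 10 iterations,
non-convergence returns the best iterate flagged). Trials are re-cut from
the continuous signal at the corrected onset. Recovered shifts are defined
only up to one common offset (shifting every trial equally leaves the
solution unchanged). The lag bound needs headroom beyond the expected
annotation jitter: trials clamped at the boundary can lock into a
misaligned subgroup (observed with a bound only 10 % above the jitter
range; the defaults leave ≥ 3× headroom).

**Spike detection** thresholds the > 300 Hz zero-phase high-passed signal at
k times the *normalized* MAD (σ̂ = MAD/0.6745, the robust noise-SD estimate
standard in extracellular sorting), default k = 6, negative crossings only
(absolute-value detection is a flag), one event per crossing group
timestamped at the trough. The raw-MAD reading of "k MADs" would put k = 6 at
only ~4σ, where Gaussian noise alone produces tens of false events per
minute at 32 kHz. Temporal whitening and clustering/template matching are
out of scope — the pipeline consumes spike times from any sorter.

**Unit quality**: RPV = percentage of ISIs < 2 ms; SUA iff RPV < 1 %
(strict) and amplitude SNR ≥ 4 — thresholds are configurable and always
reported, since published unit tables include low-RPV multi-units.
**Resting statistics** tile the recording into 10-s windows anchored at
t = 0 (partial final window dropped), keep windows overlapping no annotation,
and report FR = spikes/kept time and CV2 = mean of 2|ISIᵢ₊₁−ISIᵢ|/(ISIᵢ₊₁+ISIᵢ)
over consecutive ISI pairs within a window — the local variability measure
(1 for Poisson, 0 for clock-like), not the classic SD/mean.

**Peri-event rates** convolve the 1 ms spike histogram with a true Gaussian
density truncated at ±4σ (no reflection at edges), so the rate integral
equals the spike count for spikes ≥ 4σ inside the window. The rate–LFP
correlation ρ is the Pearson correlation of the trial-averaged 1 kHz rate
with the trial-averaged LFP. Modulation percentages use the maximal
(minimal) average rate over significant up (down) bins against the mean
pre-event-baseline bin rate: ↑ = 100·(max−B)/B, ↓ = 100·(B−min)/B (100 % =
complete silence); a direction without a significant cluster is reported
"n.s.", never 0. The global 10-s-window FR is available as an alternative
baseline behind a flag.

## Cluster-based permutation test

One condition against its own pre-event baseline. Per trial, a difference
vector is formed; a one-sample t is computed per bin across trials; bins
with two-tailed p < 0.01 form contiguous same-sign clusters scored by their
summed t ("cluster mass"); the null records, for each random sign assignment
of the per-trial difference vectors, the maximum absolute cluster mass; each
observed cluster gets the +1-corrected Monte-Carlo p-value and is reported
when p < 0.05. Monte-Carlo n = 10 000 by default. For ≤ 20 trials the full
2^n sign set can be enumerated exactly.

Two constructions of the difference vector are provided:

- **paired** (default): each bin minus a cyclically assigned *single*
  baseline bin. Under the null the two bins are identically distributed, so
  the difference is symmetric no matter how skewed low-count firing rates
  are — the sign-flip null stays calibrated. Measured familywise type-I
  error on 200 simulated homogeneous-Poisson units (50 trials × 100 bins):
  0.045–0.065 across 5–10 Hz baselines and 0.3–1.0 counts/bin, at nominal
  0.05.
- **mean** (`pairing="mean"`): each bin minus the trial's mean baseline
  rate. Lower variance, but for skewed counts the first-level t is
  left-skewed while the sign-flip null is exactly symmetric, which measured
  at 0.09–0.10 familywise type-I under the same conditions — spurious
  *down*-clusters dominate. Kept for data with near-symmetric rate
  distributions (high rates, long bins).

The correcting statistic is the maximum |cluster mass| over *both*
directions, which holds the familywise error of the whole map at 5 % while
each cluster is still compared one-sidedly at 0.05; correcting each
direction against its own maximum (a variant behind `per_direction=True`)
spends 5 % per direction and nearly doubles the two-sided familywise rate.
Zero-variance bins have no defined t and are excluded from cluster formation
with a warning. The Monte-Carlo flip sequence is seeded; the exact
enumeration path is invariant to trial order, the Monte-Carlo path is
invariant given the seed.

## Numerical choices and degenerate inputs

- Downsampling: zero-phase 8th-order Butterworth at 400 Hz, then polyphase
  resampling; output length ⌊n·1000/fs⌋; 1 kHz input returned unchanged;
  fs < 1 kHz is an error.
- EDF: 16-bit with per-channel physical scaling (quantization ≤ 1/65535 of
  the channel range); one 1 s record per second, so writing requires an
  integer sampling rate; truncated files are a format error, not silent
  truncation. Raw float32 + JSON sidecar round-trips bit-exactly.
- Periodicity: strict "< 25 %" with an epsilon guard so an interval whose
  exact deviation equals 25 % (e.g. intervals 1, 1, 2) never conforms via
  float rounding; the denominator is intervals (n−1), not deflections;
  percentages round to the nearest integer. Fewer than two deflection times
  is an error; two define the fraction but never a *periodic* train (three
  consecutive slow waves required). The interval-mode histogram (default
  1 s bins) resolves ties to the smaller interval.
- Empty/missing inputs: an absent pattern label epochs to an empty matrix
  with a warning; an empty spike train yields all-zero rates; zero baseline
  power or zero baseline rate raise explicit errors naming the quantity.

## Problem sizes in tests and drivers

Tests and drivers synthesize directly at 1 kHz (the generator's fast path;
32 kHz synthesis is exercised where the action-potential band is needed,
i.e. spike detection) with ~20–110 events per pattern, 50–100 trials per
statistical test, and 500–1000 permutations in simulation ladders
(10 000 remains the analysis default). The type-I calibration suite uses
200 null units; the spectral-recovery suite covers all 11 preset × pattern
combinations at ~100 events each.

## Known limitations

- The generator's waveform morphology is qualitative; only spectral peaks,
  event statistics and rate-gain structure are quantitative ground truth.
- Sign-flip permutation on the mean-subtracted construction is
  anti-conservative for very low firing rates (see above); the paired
  construction trades ~√2 first-level SNR for calibration.
- Alignment is integer-sample (no sub-sample interpolation) and
  single-channel; macroelectrode volume conduction is not modeled beyond
  optional attenuated copies.
- Seizure analysis is descriptive by design; no rate statistics are
  computed on seizure counts this small.
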