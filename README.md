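# ehtphysio

Functional phenotyping analytics for engineered heart tissue (EHT) and
hiPSC-derived cardiomyocytes, with a label-free proteomics
differential-abundance chain. The package targets the readouts used to
characterize contractile and Ca²⁺-handling phenotypes such as the PLN
p.Arg14del cardiomyopathy model: contraction kinetics, a beat-to-beat
irregularity statistic, Fura-2 Ca²⁺-transient decay analysis with the
caffeine SR-load protocol, and moderated-t differential protein abundance.
Every analyzer is paired with a synthetic-data generator carrying full
ground truth, so the whole chain is verifiable without any raw recordings.

## What it computes

**Contraction / Ca²⁺ traces** (uniformly sampled force in mN or Fura-2
ratio):

- beat detection by topographic prominence; per-beat baseline, amplitude,
  time-to-peak from the −80 % level (TTP₋₈₀%), relaxation time to 80 %
  decay (RT₈₀%), and RT₈₀%/force ratio, with threshold crossings located
  by linear interpolation;
- per-recording summaries: mean force, frequency = 60 / mean(RR),
  averaged absolute and peak-normalized contraction waveforms;
- **RR scatter**, the interdecile range (90th − 10th percentile, type-7)
  of beat-to-beat intervals — a surrogate for irregular beating;
- Ca²⁺-transient metrics: diastolic level, amplitude, time to 80 % decay
  (DT₈₀%) and decay constant τ from a monoexponential fit
  y(t) = y₀ + A·e^(−t/τ) over the peak → 95 %-decay window (for an exact
  exponential, DT₈₀% = τ·ln 5);
- the pacing-off / caffeine-bolus protocol: caffeine-transient amplitude
  relative to the mean twitch amplitude as an index of SR Ca²⁺ load.

**Proteomics** (proteins × samples precursor peak areas, two groups):
total-peak-area normalization scaled to grand mean 100 → missing-value
filter (drop > 30 % missing overall, except > 90 % missing in one group
and < 10 % in the other, kept with zeros imputed) → KNN imputation
(k = 3, protein rows) → log₂(x+1) → empirical-Bayes moderated t with
Benjamini–Hochberg FDR, plus sample-space PCA with the ≥ 90 %-variance
retention rule. The moderated statistic shrinks each protein's pooled
variance s² toward a prior s₀² with d₀ df estimated across proteins
(s̃² = (d₀s₀² + d·s²)/(d₀+d), t referred to d₀+d df); it reproduces
limma's `eBayes` to numerical precision (cross-checked in the tests).

## Worked example

```python
from ehtphysio import (BeatWaveformParams, RhythmParams, RecordingParams,
                       simulate_contraction_trace, detect_beats,
                       measure_transient)

wf = BeatWaveformParams(baseline=0.8, amplitude_mean=0.5, rise_duration=0.1,
                        decay_tau=0.27153, kind="ca")
trace, truth = simulate_contraction_trace(
    wf, RhythmParams(mean_rr=5.0),
    RecordingParams(duration=4.0, sample_rate=1000))
(beat,) = detect_beats(trace)
m = measure_transient(trace, beat)
print(f"DT80% = {m.dt80:.3f} s, tau = {m.tau:.3f} s")
```

prints `DT80% = 0.437 s, tau = 0.272 s` — the 80 %-decay time of a
transient with τ = 0.27153 s is τ·ln 5 ≈ 0.437 s, and the fit recovers τ
exactly on noiseless input.

The `analysis/` scripts run the full study-style workflow on simulated
cohorts (run them in order from the repository root; outputs land in
`results/`). `analysis/02_contractility.py` ends with

```
force:  control 0.137 mN vs mutant 0.067 mN  (-50.8 %, rank-sum p = 6.8e-08)
rate:   control 81.0 BPM vs mutant 98.0 BPM  (+21.0 %)
```

i.e. the disease-line cohort develops half the force and beats faster, and
`analysis/04_proteomics.py` reports the hit count, realized FDR against
the planted truth and the PCA retention. A command-line interface mirrors
the library (`ehtphysio simulate|traces|ca|proteomics`, see `--help`).

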