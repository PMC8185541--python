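# Methods

This note documents the models, conventions and parameter choices behind
`ehtphysio`, what the synthetic generators do and do not emulate, and the
package's known limitations.

## Beat model and kinetic conventions

A beat is modeled as a baseline-anchored rise (linear by default,
half-cosine optional) of duration `rise_duration` to a peak amplitude A,
followed by a monoexponential decay with time constant τ that runs until
the next onset. This waveform was chosen because every kinetic metric has
a closed form — TTP₋₈₀% = 0.8·rise_duration for a linear rise, and
RT₈₀% = DT₈₀% = τ·ln 5 for the exponential decay — so the analyzers can be
verified exactly on noiseless input. No mechanistic claim is attached: it
is an analysis-validation waveform, not an electrophysiological model.

Kinetic definitions (all crossings by linear interpolation between
bracketing samples):

- **baseline** — signal value at the beat onset; **amplitude** — peak
  value minus baseline;
- **TTP₋₈₀%** — time from the upstroke crossing baseline + 0.2·amplitude
  (the level 80 % below the peak) to the peak, following the EHT-field
  T1-80 % convention;
- **RT₈₀% / DT₈₀%** — time from the peak to the decay crossing
  baseline + 0.2·amplitude; a decay that never reaches the threshold
  inside the beat segment yields a missing value (the beat still counts
  toward frequency);
- **frequency** — 60 / mean(RR), RR being successive peak-time
  differences; continuous and unbiased for partial windows, so
  frequency·mean(RR) = 60 exactly;
- **RR scatter** — interdecile range (90th − 10th percentile, type-7
  linear interpolation of order statistics, configurable) of the raw RR
  intervals of one recording. Computed per recording; aggregation across
  recordings is left to the caller since "mean beat-to-beat distance"
  admits either reading.

### Detection

Peaks are local maxima with topographic prominence ≥ `min_prominence`
(`scipy.signal.find_peaks`) separated by ≥ `min_rr` (default 0.25 s).
When `min_prominence` is not given it defaults to
max(4 × noise SD, 5 % of the signal range) with the noise SD estimated
robustly from the MAD of successive differences. For noisy recordings a
moving-average `smooth_window` (~0.02–0.05 s) is applied to a *detection
copy* of the signal; indices (peak, onset, end) are located on that copy
but metric values are always read from the raw trace, so noiseless
closed forms stay exact. The onset is the pre-peak minimum within a
bounded lookback window (default 2·`min_rr`; it must cover the upstroke):
bounding the search keeps the extreme-value dip of noise comparable
across beat types instead of growing with the length of the preceding
quiescent stretch. The original video-optical software's onset definition
is unpublished; this is the package's convention.

Point estimates read off selected extremal samples (peak, onset) carry a
small bias of order the noise SD (extreme-value selection, and corner
rounding when detection is smoothed). At 3 % amplitude noise this is a
2–4 % effect on amplitudes; it largely cancels in within-recording ratios
and in cohort percent differences, which is what the tests quantify.

## Tau fitting and the caffeine protocol

`fit_decay_tau` performs a three-parameter least-squares fit of
y(t) = y₀ + A·e^(−t/τ) (τ > 0, A ≥ 0), initialized from a log-linear
regression on baseline-subtracted values. The fit window is the peak to
the 95 %-decay crossing (or segment end) to avoid diastolic-drift
contamination; the window is this package's convention. A fit is flagged
poor when its RMSE exceeds 5 % of the fitted amplitude **or** the fitted
τ exceeds twice the window span — the latter because a monoexponential
with τ much longer than the window reproduces a straight line arbitrarily
well, so such a τ is simply not resolved by the data.

`caffeine_analysis` splits the recording at the pacing-off time (from the
protocol metadata), takes the mean amplitude of the last five accepted
twitches, and identifies the caffeine transient as the largest-prominence
peak after pacing off (by prominence, not by time, tolerating variable
bolus delay). The caffeine/twitch amplitude ratio indexes SR Ca²⁺ load;
no fractional-release decomposition or ratio-to-concentration calibration
is attempted.

## Synthetic generators

All generators are deterministic given their seed (NumPy `default_rng`);
a pipeline-level counter scheme (`child_seed(seed, i) =
(seed + 1000003·(i+1)) mod 2³¹`) fans one seed out to recordings.

**Beat trains.** RR intervals are Gaussian (`mean_rr`, `rr_sd`, clipped
above the rise duration); an ectopic event replaces one interval by a
short coupling interval ρ·mean_rr followed by a compensatory pause
(2−ρ)·mean_rr, preserving the mean RR. An ectopic pair is only started
when the pause still fits inside the recording window — a lone coupling
interval at the window edge would length-bias the mean RR. Beat
amplitudes are log-normal with the configured CV (positivity); beats are
emitted while their full rise fits in the window, and a final truncated
decay is flagged in the ground truth. Extracellular Ca²⁺ maps affinely
and monotonically to `rr_sd` and `ectopic_prob`
(`rhythm_for_ca_load`); the slopes are qualitative — they reproduce the
ordering of irregularity across 1.0/1.8/3.0 mM, not measured magnitudes.

**Caffeine protocol.** A twitch segment paced at 0.5 Hz (default 20 s),
a pacing-off gap (default 10 s; a warning is logged when the gap is
shorter than five twitch decay constants), then exactly one caffeine
transient with amplitude `caffeine_amplitude_factor` × the mean realized
twitch amplitude and a slower decay constant (default 1.5 s, cytosolic
removal without SERCA re-uptake).

**Proteomics.** Latent per-protein log₂ intensities are Gaussian
(defaults: mean 20, SD 2 on raw peak-area scale; 1500 proteins; 12 vs 10
samples as in the emulated cohort). 10 % of proteins carry a planted
shift of magnitude 1 log₂ unit in group 2, half up and half down —
one-sided shifts would violate the balanced-composition assumption of
total-peak-area normalization and leak a spurious shift into every null
protein. Per-cell dropout probability decreases logistically with the
cell's latent log₂ intensity (defaults: intercept −3, slope 0.6, ≈ 10 %
missing overall); 3 % of the non-shifted proteins are additionally made
fully absent in one random group and fully observed in the other, the
presence/absence pattern the filter's exception branch targets. Residual
SD is 0.5 log₂ units.

What the generators do **not** emulate: mechanistic excitation–
contraction coupling, motion/video artifacts, drift and photobleaching,
correlated (non-white) noise, peptide-to-protein roll-up effects,
batch structure, or missingness mechanisms beyond
logistic-in-intensity + group absence. Passing tests therefore
demonstrate correctness of the estimators under these stated conditions,
not robustness to every artifact of real recordings.

## Proteomics chain conventions

Pipeline order is fixed: normalize → filter/zero-impute → KNN impute →
log₂ → moderated t → BH.

- *Normalization*: each sample's observed intensities are divided by that
  sample's total observed peak area, then one global constant sets the
  grand mean of observed values to 100. Idempotent.
- *Filter*: "more than 30 % missing values in all samples" is read as an
  overall missing fraction > 30 % across all samples — the only reading
  consistent with the stated exception; thresholds are strict
  inequalities (> 0.30, > 0.90, < 0.10). Exception proteins get zeros in
  the high-missing group (presence/absence evidence) and survive.
- *KNN imputation* runs over protein rows (standard for omics matrices):
  Euclidean distance over co-observed samples scaled by √(n/|shared|),
  missing cell ← mean of the k = 3 nearest proteins observed in that
  sample; a protein with no eligible neighbour falls back to its own
  observed mean.
- *log₂(x + 1)* on the grand-mean-100 scale, so zero-imputed cells map to
  exactly 0. The pseudocount compresses fold changes of low-intensity
  proteins (a protein at normalized intensity ~3 has its |log₂FC|
  attenuated by roughly a quarter); this is inherent to pseudocount
  transforms and is why estimator unbiasedness is asserted on the log₂
  scale while the end-to-end chain is held to FDR control.
- *Moderated t*: the variance prior (d₀, s₀²) is estimated by the
  method of moments on log s² (digamma/trigamma matching, Newton
  inversion of the trigamma), the standard empirical-Bayes construction;
  it agrees with limma's `fitFDist`/`eBayes` to numerical precision. A
  non-positive excess variance of log s² yields d₀ = ∞ (normal reference
  distribution). All-zero-variance input is a degenerate-prior error.
- *PCA*: proteins centered, samples decomposed (full SVD); retained
  component count is the smallest m whose cumulative explained-variance
  fraction reaches 0.90. The elbow-style scree criterion is not
  implemented; the 90 %-cumulative rule is treated as operative.

## Problem sizes used in the test-suite and acceptance runs

Monte-Carlo checks use 200–500 replicate seeds for scalar recovery
(RR moments, IDR, τ, caffeine ratio), 200 replicates of 2000 × 22
matrices for the null calibration of the moderated t, and 100 simulated
cohorts for end-to-end FDR; trace-level checks run at 100–1000 Hz over
10–60 s recordings. The cohort-force comparison uses 20 recordings per
arm of 60 s at 1 kHz. These sizes give Monte-Carlo standard errors well
below the effect sizes being verified.

## Known limitations

- The RR-scatter statistic is computed on raw per-recording intervals;
  long-horizon aggregation (e.g. over hours of recording) is the
  caller's choice.
- Amplitude point estimates carry the O(noise SD) selection bias
  discussed above; for unbiased amplitude estimation at high noise an
  averaged-waveform or model-fit estimator would be needed.
- The monoexponential decay model is assumed, not tested, for τ; the
  poor-fit flag (RMSE, unresolved τ) is the only model diagnostic.
- The differential-abundance chain supports exactly two groups with no
  covariates, mirroring the emulated design.
- Significance after KNN imputation is mildly anti-conservative in
  general (imputed values shrink within-group variance); under the
  default generator conditions the realized FDR at BH 0.05 stays under
  0.10, which is what the tests assert.
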