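"""Synthetic recordings and proteomics matrices with known ground truth.

Three generators emulate the data the analysis modules consume:

* :func:`simulate_contraction_trace` — spontaneous or paced beat trains
  (force or Fura-2 ratio channel) with optional RR jitter and ectopic
  beats, used to exercise beat detection, kinetic metrics and the
  beat-to-beat irregularity statistic.
* :func:`simulate_ca_protocol` — a paced twitch segment followed by
  pacing-off and a single caffeine-evoked Ca2+ transient, the standard
  protocol for indexing sarcoplasmic-reticulum Ca2+ load.
* :func:`simulate_proteomics` — a proteins x samples peak-area matrix with
  log-normal intensities, planted log2 fold changes, intensity-dependent
  dropout and a configurable fraction of one-group-absent proteins.

Every generator is deterministic given its seed and returns a ground-truth
record alongside the data so estimators can be validated without any real
recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trace import Trace

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class BeatWaveformParams:
    """Shape of a single beat: linear (or half-cosine) rise to the peak,
    then monoexponential decay back toward baseline.

    Units follow the signal channel: mN for force, ratio units for Ca2+.
    ``amplitude_cv`` is the coefficient of variation of the log-normal
    beat-to-beat amplitude draw (0 = identical beats).
    """

    baseline: float = 0.02
    amplitude_mean: float = 0.14
    amplitude_cv: float = 0.0
    rise_duration: float = 0.12
    decay_tau: float = 0.15
    kind: str = "force"
    rise_shape: str = "linear"  # "linear" | "cosine"

    def __post_init__(self) -> None:
        if not self.amplitude_mean > 0:
            raise ValueError("amplitude_mean must be > 0")
        if not self.rise_duration > 0:
            raise ValueError("rise_duration must be > 0")
        if not self.decay_tau > 0:
            raise ValueError("decay_tau must be > 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if self.rise_shape not in ("linear", "cosine"):
            raise ValueError("rise_shape must be 'linear' or 'cosine'")


@dataclass
class RhythmParams:
    """Beat-to-beat rhythm: mean RR interval, Gaussian RR jitter, and an
    ectopic-beat mechanism.

    An ectopic event replaces one interval by the short coupling interval
    ``ectopic_fraction * mean_rr`` followed by the compensatory pause
    ``(2 - ectopic_fraction) * mean_rr``, so the long-run mean RR is
    preserved.
    """

    mean_rr: float = 0.74
    rr_sd: float = 0.0
    ectopic_prob: float = 0.0
    ectopic_fraction: float = 0.4
    ca_load_mm: Optional[float] = None  # annotation only; see rhythm_for_ca_load

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise ValueError("mean_rr must be > 0")
        if self.rr_sd < 0:
            raise ValueError("rr_sd must be >= 0")
        if not 0 <= self.ectopic_prob < 0.5:
            raise ValueError("ectopic_prob must be in [0, 0.5)")
        if not 0 < self.ectopic_fraction < 1:
            raise ValueError("ectopic_fraction must be in (0, 1)")


def rhythm_for_ca_load(
    ca_load_mm: float,
    mean_rr: float = 0.74,
    base_rr_sd: float = 0.01,
    rr_sd_per_mm: float = 0.02,
    base_ectopic_prob: float = 0.0,
    ectopic_per_mm: float = 0.04,
    ectopic_fraction: float = 0.4,
) -> RhythmParams:
    """Map extracellular Ca2+ concentration to rhythm parameters.

    Irregularity grows with Ca2+ loading: both the RR jitter and the
    ectopic-beat probability increase affinely above the 1.0 mM reference.
    The slopes are qualitative (they reproduce the ordering of irregularity
    across 1.0 / 1.8 / 3.0 mM conditions, not any measured magnitude).
    """
    if ca_load_mm <= 0:
        raise ValueError("ca_load_mm must be > 0")
    excess = max(ca_load_mm - 1.0, 0.0)
    return RhythmParams(
        mean_rr=mean_rr,
        rr_sd=base_rr_sd + rr_sd_per_mm * excess,
        ectopic_prob=min(0.45, base_ectopic_prob + ectopic_per_mm * excess),
        ectopic_fraction=ectopic_fraction,
        ca_load_mm=ca_load_mm,
    )


@dataclass
class RecordingParams:
    """Recording window, sampling rate, additive Gaussian noise and seed."""

    duration: float = 50.0
    sample_rate: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.sample_rate < 100:
            raise ValueError("sample_rate must be >= 100 Hz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CaffeineProtocolParams:
    """Pacing-off / caffeine-bolus protocol for SR Ca2+-load assessment.

    A twitch segment paced at ``pacing_rate`` runs for ``paced_segment``
    seconds; pacing is then switched off for ``pacing_off_gap`` seconds and
    a single caffeine transient follows, with amplitude
    ``caffeine_amplitude_factor`` times the mean twitch amplitude and its
    own, slower decay constant.
    """

    paced_segment: float = 20.0
    pacing_rate: float = 0.5
    pacing_off_gap: float = 10.0
    caffeine_amplitude_factor: float = 1.0
    caffeine_decay_tau: float = 1.5
    caffeine_rise_duration: float = 0.4

    def __post_init__(self) -> None:
        if not self.paced_segment > 0 or not self.pacing_rate > 0:
            raise ValueError("paced_segment and pacing_rate must be > 0")
        if self.pacing_off_gap < 0:
            raise ValueError("pacing_off_gap must be >= 0")
        if not self.caffeine_amplitude_factor > 0:
            raise ValueError("caffeine_amplitude_factor must be > 0")
        if not self.caffeine_decay_tau > 0 or not self.caffeine_rise_duration > 0:
            raise ValueError("caffeine decay tau and rise duration must be > 0")


@dataclass
class TraceGroundTruth:
    """Generator-side truth for one simulated recording (test oracle)."""

    beat_times: np.ndarray          # true peak times, s
    amplitudes: np.ndarray          # true peak amplitudes above baseline
    rr_intervals: np.ndarray        # successive peak-time differences, s
    onsets: np.ndarray              # true onset times, s
    tau: float                      # decay constant used, s
    rise_duration: float
    baseline: float
    ectopic_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    truncated_last_decay: bool = False
    # caffeine-protocol extras (None for plain beat trains)
    pacing_end_time: Optional[float] = None
    caffeine_time: Optional[float] = None
    caffeine_amplitude: Optional[float] = None
    caffeine_tau: Optional[float] = None


# ---------------------------------------------------------------------------
# beat-train construction
# ---------------------------------------------------------------------------

def _draw_amplitudes(rng, mean, cv, n):
    # log-normal keeps amplitudes positive; parameterized so E[A] = mean
    # and SD[A]/E[A] = cv.
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return mean * np.exp(rng.normal(-sigma2 / 2.0, sigma, n))


def _render_beats(values, t, onsets, amplitudes, wf: BeatWaveformParams):
    """Paint beats onto ``values`` in place. Segment for beat i runs from its
    onset to the next onset (or the end of the recording): baseline-anchored
    rise over ``rise_duration``, then monoexponential decay."""
    n = t.size
    dt = t[1] - t[0]
    truncated = False
    for i, (t_on, amp) in enumerate(zip(onsets, amplitudes)):
        t_peak = t_on + wf.rise_duration
        t_next = onsets[i + 1] if i + 1 < len(onsets) else np.inf
        i0 = int(np.ceil(t_on / dt - 1e-9))
        i_end = n if np.isinf(t_next) else min(n, int(np.ceil(t_next / dt - 1e-9)))
        seg_t = t[i0:i_end]
        rising = seg_t <= t_peak + 1e-12
        frac = np.clip((seg_t[rising] - t_on) / wf.rise_duration, 0.0, 1.0)
        if wf.rise_shape == "cosine":
            rise_vals = wf.baseline + amp * 0.5 * (1.0 - np.cos(np.pi * frac))
        else:
            rise_vals = wf.baseline + amp * frac
        decay_t = seg_t[~rising] - t_peak
        decay_vals = wf.baseline + amp * np.exp(-decay_t / wf.decay_tau)
        values[i0:i_end] = np.concatenate([rise_vals, decay_vals])
        if i + 1 == len(onsets):
            # decay cut off by the recording window before reaching ~baseline?
            t_last = t[-1] - t_peak
            truncated = t_last < 5 * wf.decay_tau
    return truncated


def simulate_contraction_trace(
    waveform: BeatWaveformParams,
    rhythm: RhythmParams,
    rec: RecordingParams,
) -> tuple[Trace, TraceGroundTruth]:
    """Simulate one beat-train recording.

    Beats are emitted while the full rise fits in the window; a final
    truncated decay is allowed and flagged in the ground truth.  Identical
    parameters and seed give identical output.
    """
    if rhythm.mean_rr <= waveform.rise_duration:
        raise ValueError(
            "overlapping beats: mean_rr "
            f"({rhythm.mean_rr} s) must exceed rise_duration "
            f"({waveform.rise_duration} s)"
        )
    rng = np.random.default_rng(rec.seed)
    fs = rec.sample_rate
    n = int(round(rec.duration * fs))
    t = np.arange(n) / fs

    # onset sequence; first onset at half a mean interval into the window
    onsets: list[float] = []
    ectopic: list[bool] = []
    pending: list[tuple[float, bool]] = []  # queued compensatory intervals
    t_on = 0.5 * rhythm.mean_rr
    min_iv = waveform.rise_duration + 1.0 / fs
    while t_on + waveform.rise_duration <= rec.duration:
        onsets.append(t_on)
        # an ectopic pair is only started if both the coupling interval and
        # the compensatory pause fit in the window; a lone coupling interval
        # at the window edge would bias the mean RR downward
        pair_fits = (t_on + 2.0 * rhythm.mean_rr + waveform.rise_duration
                     <= rec.duration)
        if pending:
            iv, is_ect = pending.pop(0)
        elif (rhythm.ectopic_prob > 0 and pair_fits
              and rng.random() < rhythm.ectopic_prob):
            iv = rhythm.ectopic_fraction * rhythm.mean_rr
            pending.append(((2.0 - rhythm.ectopic_fraction) * rhythm.mean_rr, False))
            is_ect = True
        else:
            iv = rhythm.mean_rr
            if rhythm.rr_sd > 0:
                iv += rng.normal(0.0, rhythm.rr_sd)
            is_ect = False
        ectopic.append(is_ect)
        t_on = t_on + max(iv, min_iv)

    onsets_a = np.asarray(onsets)
    amps = _draw_amplitudes(rng, waveform.amplitude_mean, waveform.amplitude_cv,
                            len(onsets))
    values = np.full(n, waveform.baseline)
    truncated = False
    if len(onsets) > 0:
        truncated = _render_beats(values, t, onsets_a, amps, waveform)
    if rec.noise_sd > 0:
        values = values + rng.normal(0.0, rec.noise_sd, n)

    peak_times = onsets_a + waveform.rise_duration
    gt = TraceGroundTruth(
        beat_times=peak_times,
        amplitudes=amps,
        rr_intervals=np.diff(peak_times),
        onsets=onsets_a,
        tau=waveform.decay_tau,
        rise_duration=waveform.rise_duration,
        baseline=waveform.baseline,
        ectopic_flags=np.asarray(ectopic, dtype=bool),
        truncated_last_decay=truncated,
    )
    meta = {
        "signal_kind": waveform.kind,
        "seed": rec.seed,
        "mean_rr_s": rhythm.mean_rr,
    }
    if rhythm.ca_load_mm is not None:
        meta["ca_mm"] = rhythm.ca_load_mm
    return Trace(dt=1.0 / fs, values=values, signal_kind=waveform.kind,
                 metadata=meta), gt


def simulate_ca_protocol(
    waveform: BeatWaveformParams,
    protocol: CaffeineProtocolParams,
    rec: RecordingParams,
) -> tuple[Trace, TraceGroundTruth]:
    """Simulate the pacing-off / caffeine SR-load protocol.

    The paced twitch segment is followed by a quiescent gap (pacing
    switched off, last twitch decays freely) and exactly one caffeine
    transient whose amplitude is ``caffeine_amplitude_factor`` times the
    mean realized twitch amplitude and whose decay constant is the slower
    ``caffeine_decay_tau`` (cytosolic Ca2+ removal without SERCA re-uptake).
    """
    if protocol.pacing_off_gap < 5 * waveform.decay_tau:
        logger.warning(
            "pacing_off_gap (%.2f s) is shorter than 5 decay taus (%.2f s); "
            "the last twitch may contaminate the caffeine segment",
            protocol.pacing_off_gap, 5 * waveform.decay_tau,
        )
    pace_iv = 1.0 / protocol.pacing_rate
    if pace_iv <= waveform.rise_duration:
        raise ValueError("pacing interval must exceed rise_duration")
    t_caf_on = protocol.paced_segment + protocol.pacing_off_gap
    needed = t_caf_on + protocol.caffeine_rise_duration + protocol.caffeine_decay_tau
    if rec.duration < needed:
        raise ValueError(
            f"recording too short for protocol: need >= {needed:.1f} s, "
            f"got {rec.duration:.1f} s"
        )
    rng = np.random.default_rng(rec.seed)
    fs = rec.sample_rate
    n = int(round(rec.duration * fs))
    t = np.arange(n) / fs

    onsets = []
    t_on = 0.5 * pace_iv
    while t_on + waveform.rise_duration <= protocol.paced_segment:
        onsets.append(t_on)
        t_on += pace_iv
    if not onsets:
        raise ValueError("paced segment too short for a single twitch")
    onsets_a = np.asarray(onsets)
    amps = _draw_amplitudes(rng, waveform.amplitude_mean, waveform.amplitude_cv,
                            len(onsets))
    values = np.full(n, waveform.baseline)
    _render_beats(values, t, onsets_a, amps, waveform)

    caf_amp = protocol.caffeine_amplitude_factor * float(np.mean(amps))
    caf_wf = BeatWaveformParams(
        baseline=waveform.baseline,
        amplitude_mean=caf_amp,
        amplitude_cv=0.0,
        rise_duration=protocol.caffeine_rise_duration,
        decay_tau=protocol.caffeine_decay_tau,
        kind=waveform.kind,
        rise_shape=waveform.rise_shape,
    )
    _render_beats(values, t, np.array([t_caf_on]), np.array([caf_amp]), caf_wf)
    if rec.noise_sd > 0:
        values = values + rng.normal(0.0, rec.noise_sd, n)

    peak_times = onsets_a + waveform.rise_duration
    gt = TraceGroundTruth(
        beat_times=peak_times,
        amplitudes=amps,
        rr_intervals=np.diff(peak_times),
        onsets=onsets_a,
        tau=waveform.decay_tau,
        rise_duration=waveform.rise_duration,
        baseline=waveform.baseline,
        pacing_end_time=protocol.paced_segment,
        caffeine_time=t_caf_on + protocol.caffeine_rise_duration,
        caffeine_amplitude=caf_amp,
        caffeine_tau=protocol.caffeine_decay_tau,
    )
    meta = {
        "signal_kind": waveform.kind,
        "seed": rec.seed,
        "pacing_end_s": protocol.paced_segment,
        "pacing_rate_hz": protocol.pacing_rate,
        "protocol": "caffeine",
    }
    return Trace(dt=1.0 / fs, values=values, signal_kind=waveform.kind,
                 metadata=meta), gt


# ---------------------------------------------------------------------------
# proteomics matrix
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsSimParams:
    """Label-free proteomics simulation.

    Per-protein latent log2 intensities are Gaussian; a ``de_fraction`` of
    proteins carries a planted shift of magnitude ``log2fc_effect`` in
    group 2 (``de_up_fraction`` of them up, the rest down, so the total
    intensity stays balanced between groups).  Per-cell
    dropout probability decreases logistically with the cell's latent log2
    intensity (``expit(dropout_intercept - dropout_slope * (x - mean))``),
    and ``group_dropout_fraction`` of the non-shifted proteins are made
    absent in one randomly chosen group (the presence/absence pattern the
    missing-value filter's exception branch targets).
    """

    n_proteins: int = 1500
    n_samples_group1: int = 12
    n_samples_group2: int = 10
    log2_intensity_mean: float = 20.0
    log2_intensity_sd: float = 2.0
    de_fraction: float = 0.10
    log2fc_effect: float = 1.0
    de_up_fraction: float = 0.5  # fraction of shifted proteins going up
    residual_sd: float = 0.5
    dropout_slope: float = 0.6
    dropout_intercept: float = -3.0
    group_dropout_fraction: float = 0.03
    group_labels: tuple[str, str] = ("control", "mutant")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.n_samples_group1 < 2 or self.n_samples_group2 < 2:
            raise ValueError("each group needs >= 2 samples")
        for name in ("de_fraction", "group_dropout_fraction",
                     "de_up_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.group_dropout_fraction > 1 - self.de_fraction:
            raise ValueError(
                "group_dropout_fraction exceeds the non-DE fraction "
                f"(1 - de_fraction = {1 - self.de_fraction:.2f})"
            )
        if self.residual_sd < 0 or self.log2_intensity_sd < 0:
            raise ValueError("sd parameters must be >= 0")


@dataclass
class ProteomicsGroundTruth:
    """Planted structure of a simulated abundance matrix (test oracle)."""

    de_mask: np.ndarray            # proteins with a planted shift
    true_log2fc: np.ndarray        # per-protein planted log2 FC (group2 - group1)
    group_dropout_mask: np.ndarray  # proteins absent in one group
    group_dropout_group: np.ndarray  # 1 or 2 for masked proteins, 0 otherwise
    missing_mask: np.ndarray       # realized proteins x samples missingness
    latent_log2: np.ndarray        # noise-free per-cell log2 intensities


def simulate_proteomics(
    params: ProteomicsSimParams,
) -> tuple["AbundanceMatrix", ProteomicsGroundTruth]:
    """Simulate a proteins x samples peak-area matrix with known truth."""
    from .proteomics import AbundanceMatrix  # local import to avoid a cycle

    p = params
    rng = np.random.default_rng(p.seed)
    n1, n2 = p.n_samples_group1, p.n_samples_group2
    m = n1 + n2
    group2 = np.zeros(m, dtype=bool)
    group2[n1:] = True

    mu = rng.normal(p.log2_intensity_mean, p.log2_intensity_sd, p.n_proteins)
    n_de = int(round(p.de_fraction * p.n_proteins))
    n_gd = int(round(p.group_dropout_fraction * p.n_proteins))
    order = rng.permutation(p.n_proteins)
    de_idx = order[:n_de]
    gd_idx = order[n_de:n_de + n_gd]  # disjoint from the DE set
    de_mask = np.zeros(p.n_proteins, dtype=bool)
    de_mask[de_idx] = True
    # signed effects: one-sided shifts would break total-peak-area
    # normalization (compositional bias onto every null protein)
    n_up = int(round(p.de_up_fraction * n_de))
    true_fc = np.zeros(p.n_proteins)
    true_fc[de_idx[:n_up]] = p.log2fc_effect
    true_fc[de_idx[n_up:]] = -p.log2fc_effect

    log2x = mu[:, None] + true_fc[:, None] * group2[None, :]
    log2x = log2x + rng.normal(0.0, p.residual_sd, (p.n_proteins, m))

    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(-(p.dropout_intercept
                                       - p.dropout_slope
                                       * (log2x - p.log2_intensity_mean))))
    missing = rng.random((p.n_proteins, m)) < p_miss

    gd_mask = np.zeros(p.n_proteins, dtype=bool)
    gd_mask[gd_idx] = True
    gd_group = np.zeros(p.n_proteins, dtype=np.int8)
    for i in gd_idx:
        g = 1 + int(rng.random() < 0.5)
        gd_group[i] = g
        in_g = group2 if g == 2 else ~group2
        missing[i, in_g] = True     # fully absent in the chosen group
        missing[i, ~in_g] = False   # fully observed in the other

    intensities = np.exp2(log2x)
    intensities[missing] = np.nan

    protein_ids = [f"P{i:05d}" for i in range(p.n_proteins)]
    sample_ids = ([f"{p.group_labels[0]}_{j + 1:02d}" for j in range(n1)]
                  + [f"{p.group_labels[1]}_{j + 1:02d}" for j in range(n2)])
    data = pd.DataFrame(intensities, index=protein_ids, columns=sample_ids)
    groups = pd.Series(
        [p.group_labels[0]] * n1 + [p.group_labels[1]] * n2,
        index=sample_ids, name="group",
    )
    gt = ProteomicsGroundTruth(
        de_mask=de_mask,
        true_log2fc=true_fc,
        group_dropout_mask=gd_mask,
        group_dropout_group=gd_group,
        missing_mask=missing,
        latent_log2=log2x,
    )
    return AbundanceMatrix(data=data, groups=groups), gt
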