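"""Beat detection and contraction-kinetics metrics.

Workflow: :func:`detect_beats` finds peaks and assigns each a segment
(onset = pre-peak local minimum, end = next onset or 95 % decay), then
:func:`measure_beat` computes per-beat kinetics (amplitude, TTP-80%,
RT80%), :func:`summarize_trace` aggregates a recording, and
:func:`compare_cohorts` reports group means, percent differences and
rank-sum p-values across recordings.

Conventions
-----------
* TTP-80% is the time from the upstroke crossing 20 % of the amplitude
  (the "-80 %" level below the peak) to the peak.
* RT80% (and DT80% on the Ca2+ channel) is the time from the peak to the
  decay crossing 80 % of the amplitude; both crossings are located by
  linear interpolation between bracketing samples.
* RR intervals are successive peak-time differences; frequency is
  60 / mean(RR); the irregularity statistic is the interdecile range of
  the RR intervals (type-7 percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .trace import Trace

DEFAULT_COHORT_METRICS = (
    "mean_force",
    "frequency_bpm",
    "rr_scatter_idr",
    "mean_ttp_m80",
    "mean_rt80",
    "mean_rt80_over_amplitude",
)


@dataclass
class Beat:
    """Half-open beat segment [onset, end) with its peak sample index."""

    onset: int
    peak: int
    end: int

    def __post_init__(self) -> None:
        if not self.onset < self.peak < self.end:
            raise ValueError(
                f"beat indices must satisfy onset < peak < end, got "
                f"({self.onset}, {self.peak}, {self.end})"
            )


@dataclass
class BeatMetrics:
    """Kinetic metrics of one beat; NaN marks a metric that could not be
    evaluated inside the beat segment (e.g. truncated decay)."""

    baseline: float
    amplitude: float
    ttp_m80: float
    rt80: float
    rt80_over_amplitude: float

    @property
    def accepted(self) -> bool:
        return self.amplitude > 0


@dataclass
class TraceSummary:
    """Per-recording aggregates over accepted beats."""

    n_beats: int
    mean_force: float
    frequency_bpm: float
    rr_intervals: np.ndarray
    rr_scatter_idr: float
    mean_ttp_m80: float
    mean_rt80: float
    mean_rt80_over_amplitude: float
    avg_peak_absolute: Optional[np.ndarray] = None
    avg_peak_normalized: Optional[np.ndarray] = None
    avg_peak_dt: Optional[float] = None
    metadata: dict = field(default_factory=dict)


def _estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from the median absolute successive difference.

    Successive differences of a smooth signal are small, so their MAD is
    dominated by the noise; /sqrt(2) undoes the difference variance.
    """
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6744897501960817
                 / np.sqrt(2.0))


def detect_beats(
    trace: Trace,
    min_prominence: Optional[float] = None,
    min_rr: float = 0.25,
    smooth_window: float = 0.0,
    onset_lookback: Optional[float] = None,
) -> list[Beat]:
    """Detect beats as prominent local maxima.

    Parameters
    ----------
    min_prominence
        Topographic prominence threshold in signal units.  ``None``
        auto-selects ``max(4 * noise_sd, 5 % of the signal range)`` with the
        noise SD estimated robustly from successive differences.
    min_rr
        Minimum peak separation in seconds.
    smooth_window
        Moving-average window (s) applied to a detection copy of the
        signal; 0 disables smoothing.  Peak/onset indices are located on
        the smoothed copy, metric values are always read from the raw
        trace.  Use ~0.02-0.05 s for noisy recordings.
    onset_lookback
        How far before each peak (s) to search for its onset minimum;
        defaults to ``2 * min_rr``.  Must cover the upstroke duration.

    Returns an ordered, non-overlapping list of beats: onset = pre-peak
    minimum (the diastolic point before the upstroke), end = next onset or
    the first sample after 95 % decay, whichever is earlier.
    """
    if min_prominence is not None and not min_prominence > 0:
        raise ValueError("min_prominence must be > 0")
    v = trace.values
    dt = trace.dt
    if smooth_window > 0:
        w = max(1, int(round(smooth_window / dt)))
        s = ndimage.uniform_filter1d(v, size=w, mode="nearest")
    else:
        s = v
    rng_span = float(np.ptp(s))
    if rng_span == 0:
        return []
    if min_prominence is None:
        min_prominence = max(4.0 * _estimate_noise_sd(v), 0.05 * rng_span)
    distance = max(1, int(round(min_rr / dt)))
    peaks, _ = signal.find_peaks(s, prominence=min_prominence, distance=distance)
    if peaks.size == 0:
        return []

    if onset_lookback is None:
        onset_lookback = 2.0 * min_rr
    lb = max(1, int(round(onset_lookback / dt)))
    beats: list[Beat] = []
    onsets = np.empty(peaks.size, dtype=int)
    for i, pk in enumerate(peaks):
        lo = 0 if i == 0 else int(peaks[i - 1])
        # pre-peak minimum within a bounded lookback window; the bound keeps
        # the extreme-value dip of noise comparable across beat types instead
        # of growing with the length of the preceding quiescent stretch
        start = max(lo, pk - lb)
        onsets[i] = start + int(np.argmin(s[start:pk + 1]))
    for i, pk in enumerate(peaks):
        onset = onsets[i]
        if onset >= pk:
            continue
        nxt = onsets[i + 1] if i + 1 < peaks.size else s.size
        amp = s[pk] - s[onset]
        thr = s[onset] + 0.05 * amp
        below = np.nonzero(s[pk:nxt] <= thr)[0]
        end = pk + int(below[0]) + 1 if below.size else nxt
        end = min(end, nxt)
        if end <= pk:
            end = pk + 1
        beats.append(Beat(onset=onset, peak=pk, end=end))
    return beats


def _interp_crossing_time(t0: float, t1: float, y0: float, y1: float,
                          level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def measure_beat(
    trace: Trace,
    beat: Beat,
    rise_fraction: float = 0.80,
    decay_fraction: float = 0.80,
) -> BeatMetrics:
    """Kinetics of one beat.

    baseline = value at onset; amplitude = peak - baseline; ``ttp_m80`` =
    time from the upstroke crossing ``baseline + (1-rise_fraction)*amp`` to
    the peak; ``rt80`` = time from the peak to the decay crossing
    ``baseline + (1-decay_fraction)*amp``.  A decay that never reaches its
    threshold inside the segment yields ``rt80 = NaN`` (beat retained).
    """
    v = trace.values
    dt = trace.dt
    if not (0 <= beat.onset < beat.peak < beat.end <= v.size):
        raise ValueError("beat indices out of range for trace")
    baseline = float(v[beat.onset])
    amplitude = float(v[beat.peak]) - baseline
    if amplitude <= 0:
        return BeatMetrics(baseline, amplitude, np.nan, np.nan, np.nan)

    rise_level = baseline + (1.0 - rise_fraction) * amplitude
    ttp = np.nan
    for j in range(beat.peak - 1, beat.onset - 1, -1):
        if v[j] <= rise_level:
            tc = _interp_crossing_time(j * dt, (j + 1) * dt, v[j], v[j + 1],
                                       rise_level)
            ttp = beat.peak * dt - tc
            break
    if np.isnan(ttp):
        ttp = (beat.peak - beat.onset) * dt  # level never reached; whole rise

    decay_level = baseline + (1.0 - decay_fraction) * amplitude
    rt = np.nan
    seg = v[beat.peak:beat.end]
    below = np.nonzero(seg <= decay_level)[0]
    if below.size:
        j = beat.peak + int(below[0])
        tc = _interp_crossing_time((j - 1) * dt, j * dt, v[j - 1], v[j],
                                   decay_level)
        rt = tc - beat.peak * dt
    return BeatMetrics(
        baseline=baseline,
        amplitude=amplitude,
        ttp_m80=float(ttp),
        rt80=float(rt),
        rt80_over_amplitude=float(rt / amplitude),
    )


def rr_scatter(
    rr_intervals: Sequence[float],
    lower: float = 10.0,
    upper: float = 90.0,
    method: str = "linear",
) -> float:
    """Interdecile range of beat-to-beat intervals (irregularity surrogate).

    90th minus 10th percentile, percentiles by linear interpolation of
    order statistics (type-7 convention, configurable via ``method``).
    Returns NaN for fewer than 2 intervals.
    """
    rr = np.asarray(rr_intervals, dtype=float)
    if rr.size < 2:
        return float("nan")
    lo, hi = np.percentile(rr, [lower, upper], method=method)
    return float(hi - lo)


def average_peaks(
    trace: Trace,
    beats: Sequence[Beat],
    mode: str = "absolute",
    window: float = 0.3,
) -> np.ndarray:
    """Average beat waveform aligned at the peak over [-window, +window].

    Beats are baseline-subtracted; in ``"normalized"`` mode each beat is
    divided by its own amplitude before averaging and the average is pinned
    to maximum 1.  Beats whose window does not fit in the recording are
    skipped; no eligible beat is an error.
    """
    if mode not in ("absolute", "normalized"):
        raise ValueError("mode must be 'absolute' or 'normalized'")
    v = trace.values
    nw = int(round(window / trace.dt))
    segs = []
    for b in beats:
        if b.peak - nw < 0 or b.peak + nw + 1 > v.size:
            continue
        m = measure_beat(trace, b)
        if not m.accepted:
            continue
        seg = v[b.peak - nw:b.peak + nw + 1] - m.baseline
        if mode == "normalized":
            seg = seg / m.amplitude
        segs.append(seg)
    if not segs:
        raise ValueError("no beat with a complete averaging window")
    avg = np.mean(segs, axis=0)
    if mode == "normalized":
        avg = avg / np.max(avg)
    return avg


def summarize_trace(
    trace: Trace,
    beats: Sequence[Beat],
    avg_window: Optional[float] = None,
) -> TraceSummary:
    """Aggregate per-beat metrics into a recording summary.

    Fewer than 2 beats leaves frequency (and with < 3 beats, RR scatter)
    as NaN rather than zero.  Beats with truncated decays contribute to
    frequency but are excluded from the kinetic means.
    """
    metrics = [measure_beat(trace, b) for b in beats]
    accepted = [(b, m) for b, m in zip(beats, metrics) if m.accepted]
    amps = np.array([m.amplitude for _, m in accepted])
    peak_times = np.array([b.peak * trace.dt for b, _ in accepted])
    rr = np.diff(peak_times)

    def _nanmean(x):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        return float(x.mean()) if x.size else float("nan")

    freq = 60.0 / rr.mean() if rr.size >= 1 and len(accepted) >= 2 else float("nan")
    if avg_window is None:
        avg_window = 0.4 * float(np.median(rr)) if rr.size else 0.3
    avg_abs = avg_norm = None
    try:
        avg_abs = average_peaks(trace, [b for b, _ in accepted], "absolute",
                                avg_window)
        avg_norm = average_peaks(trace, [b for b, _ in accepted], "normalized",
                                 avg_window)
    except ValueError:
        pass
    return TraceSummary(
        n_beats=len(accepted),
        mean_force=_nanmean(amps),
        frequency_bpm=float(freq),
        rr_intervals=rr,
        rr_scatter_idr=rr_scatter(rr),
        mean_ttp_m80=_nanmean([m.ttp_m80 for _, m in accepted]),
        mean_rt80=_nanmean([m.rt80 for _, m in accepted]),
        mean_rt80_over_amplitude=_nanmean(
            [m.rt80_over_amplitude for _, m in accepted]),
        avg_peak_absolute=avg_abs,
        avg_peak_normalized=avg_norm,
        avg_peak_dt=trace.dt,
        metadata=dict(trace.metadata),
    )


def compare_cohorts(
    summaries_a: Sequence[TraceSummary],
    summaries_b: Sequence[TraceSummary],
    metrics: Sequence[str] = DEFAULT_COHORT_METRICS,
) -> pd.DataFrame:
    """Descriptive two-cohort comparison.

    For each metric: group means +/- SEM, percent difference of B relative
    to A (``100 * (mean_B - mean_A) / mean_A``) and a two-sided
    Mann-Whitney rank-sum p-value (reported, not interpreted).
    """
    if len(summaries_a) < 2 or len(summaries_b) < 2:
        raise ValueError("each cohort needs >= 2 recordings")
    for name in metrics:
        if not hasattr(summaries_a[0], name):
            raise ValueError(f"unknown metric {name!r}")
    rows = []
    for name in metrics:
        a = np.array([getattr(s, name) for s in summaries_a], dtype=float)
        b = np.array([getattr(s, name) for s in summaries_b], dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size == 0 or b.size == 0:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                         a.size, b.size))
            continue
        ma, mb = a.mean(), b.mean()
        sem_a = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else np.nan
        sem_b = b.std(ddof=1) / np.sqrt(b.size) if b.size > 1 else np.nan
        pct = 100.0 * (mb - ma) / ma if ma != 0 else np.nan
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0  # identical constant cohorts; rank-sum is undefined
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((name, ma, sem_a, mb, sem_b, pct, p, a.size, b.size))
    return pd.DataFrame(
        rows,
        columns=["metric", "mean_a", "sem_a", "mean_b", "sem_b",
                 "pct_diff_b_vs_a", "p_ranksum", "n_a", "n_b"],
    ).set_index("metric")
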