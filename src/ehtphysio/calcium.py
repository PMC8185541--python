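"""Fura-2 Ca2+-transient kinetics and the caffeine SR-load protocol.

A Ca2+ transient is characterized by its diastolic level, amplitude, time
to 80 % decay (DT80%) and the time constant tau of a monoexponential fit
to the post-peak decay.  For an exact exponential the two decay metrics
are linked by DT80% = tau * ln 5.

The caffeine protocol (pacing switched off, single caffeine bolus) indexes
sarcoplasmic-reticulum Ca2+ load: :func:`caffeine_analysis` reports the
caffeine-transient amplitude relative to the mean twitch amplitude and the
caffeine decay constant (cytosolic removal without SERCA re-uptake).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .beats import Beat, detect_beats, measure_beat
from .trace import Trace

logger = logging.getLogger(__name__)

#: fit RMSE above this fraction of the amplitude flags a poor fit
POOR_FIT_RMSE_FRACTION = 0.05


@dataclass
class DecayFit:
    """Monoexponential decay fit y(t) = baseline + A * exp(-t / tau)."""

    tau: float
    rmse: float
    baseline: float
    amplitude: float
    ok: bool
    poor_fit: bool
    message: str = ""


@dataclass
class CaTransientMetrics:
    """Per-transient metrics (ratio units / seconds)."""

    diastolic: float
    amplitude: float
    dt80: float
    tau: float
    fit_rmse: float
    poor_fit: bool


@dataclass
class CaffeineResult:
    twitch_amplitude_mean: float
    caffeine_amplitude: float
    caffeine_ratio: float
    caffeine_tau: float
    caffeine_peak_time: float


def fit_decay_tau(times: np.ndarray, values: np.ndarray) -> DecayFit:
    """Least-squares monoexponential fit to a decay segment.

    ``times`` must start at the peak (t=0) and increase; the fit window is
    the caller's responsibility (see :func:`measure_transient`, which uses
    peak to 95 % decay).  Initialization: baseline from the segment tail,
    tau from a log-linear regression on baseline-subtracted values.  A fit
    whose RMSE exceeds 5 % of the fitted amplitude is flagged poor (e.g.
    non-exponential decays); non-convergence returns ``ok=False``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 10:
        raise ValueError(f"decay segment needs >= 10 samples, got {t.size}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("decay segment contains non-finite values")

    b0 = float(np.min(y))
    a0 = float(y[0] - b0)
    if a0 <= 0:
        return DecayFit(np.nan, np.nan, b0, a0, False, True,
                        "segment does not decay")
    # log-linear initialization on the clearly-above-baseline part
    resid = y - b0
    mask = resid > 0.05 * a0
    if mask.sum() >= 3:
        slope, intercept = np.polyfit(t[mask], np.log(resid[mask]), 1)
        tau0 = -1.0 / slope if slope < 0 else t[-1]
    else:
        tau0 = max(t[-1] / 3.0, 10 * (t[1] - t[0]))
    tau0 = float(np.clip(tau0, 1e-6, 1e6))

    def model(tt, b, a, tau):
        return b + a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[b0, a0, tau0],
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, 1e9]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        logger.warning("tau fit did not converge: %s", exc)
        return DecayFit(np.nan, np.nan, b0, a0, False, True, str(exc))
    b, a, tau = (float(x) for x in popt)
    rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    span = float(t[-1] - t[0])
    # tau far beyond the window means the segment is indistinguishable from
    # a straight line -- the decay constant is not resolved by the data
    poor = (a <= 0 or rmse > POOR_FIT_RMSE_FRACTION * max(a, 1e-12)
            or tau > 2.0 * span)
    return DecayFit(tau, rmse, b, a, True, poor)


def measure_transient(
    trace: Trace,
    beat: Beat,
    decay_fraction: float = 0.80,
) -> CaTransientMetrics:
    """Metrics of one Ca2+ transient.

    diastolic = value at onset, amplitude = peak - diastolic, DT80% = time
    from peak to the 80 %-decay crossing (linear interpolation), tau from a
    monoexponential fit over peak to 95 % decay (or the segment end).
    """
    m = measure_beat(trace, beat, decay_fraction=decay_fraction)
    v = trace.values
    dt = trace.dt
    tau = rmse = float("nan")
    poor = True
    if m.accepted:
        lvl95 = m.baseline + 0.05 * m.amplitude
        seg = v[beat.peak:beat.end]
        below = np.nonzero(seg <= lvl95)[0]
        stop = beat.peak + int(below[0]) + 1 if below.size else beat.end
        if stop - beat.peak >= 10:
            t_rel = (np.arange(beat.peak, stop) - beat.peak) * dt
            fit = fit_decay_tau(t_rel, v[beat.peak:stop])
            if fit.ok:
                tau, rmse, poor = fit.tau, fit.rmse, fit.poor_fit
    return CaTransientMetrics(
        diastolic=m.baseline,
        amplitude=m.amplitude,
        dt80=m.rt80,
        tau=tau,
        fit_rmse=rmse,
        poor_fit=poor,
    )


def caffeine_analysis(
    trace: Trace,
    pacing_end_s: Optional[float] = None,
    min_prominence: Optional[float] = None,
    min_rr: float = 0.25,
    smooth_window: float = 0.0,
    n_twitch: int = 5,
) -> CaffeineResult:
    """Analyze a pacing-off / caffeine-bolus recording.

    The paced segment (up to ``pacing_end_s``, taken from the trace
    metadata when not given) provides the mean amplitude of the last
    ``n_twitch`` accepted twitches; the caffeine transient is the
    largest-prominence peak after pacing off (tolerant of a variable
    bolus-application delay), measured like any transient plus a tau fit.
    """
    if pacing_end_s is None:
        pacing_end_s = trace.metadata.get("pacing_end_s")
    if pacing_end_s is None:
        raise ValueError("pacing_end_s not given and absent from metadata")
    split = int(round(pacing_end_s / trace.dt))
    if not 1 < split < trace.n_samples - 1:
        raise ValueError("pacing_end_s outside the recording")

    paced = Trace(trace.dt, trace.values[:split], trace.signal_kind)
    twitch_beats = detect_beats(paced, min_prominence=min_prominence,
                                min_rr=min_rr, smooth_window=smooth_window)
    twitch_amps = [m.amplitude for m in
                   (measure_beat(paced, b) for b in twitch_beats) if m.accepted]
    if not twitch_amps:
        raise ValueError("no twitch detected in the paced segment")
    twitch_mean = float(np.mean(twitch_amps[-n_twitch:]))

    post = Trace(trace.dt, trace.values[split:], trace.signal_kind)
    post_beats = detect_beats(post, min_prominence=min_prominence,
                              min_rr=min_rr, smooth_window=smooth_window)
    if not post_beats:
        raise ValueError("no caffeine transient: no peak above the "
                         "prominence threshold after pacing off")
    # caffeine transient = the most prominent post-pacing event
    caf = max(post_beats,
              key=lambda b: post.values[b.peak] - post.values[b.onset])
    cm = measure_transient(post, caf)
    return CaffeineResult(
        twitch_amplitude_mean=twitch_mean,
        caffeine_amplitude=cm.amplitude,
        caffeine_ratio=cm.amplitude / twitch_mean,
        caffeine_tau=cm.tau,
        caffeine_peak_time=(split + caf.peak) * trace.dt,
    )
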