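import numpy as np
import pytest

from ehtphysio import (BeatWaveformParams, RecordingParams, RhythmParams,
                       simulate_contraction_trace)


@pytest.fixture
def force_waveform():
    return BeatWaveformParams(baseline=0.02, amplitude_mean=0.14,
                              amplitude_cv=0.0, rise_duration=0.10,
                              decay_tau=0.15, kind="force")


@pytest.fixture
def noiseless_train(force_waveform):
    """10 identical beats at exactly 1.0 s spacing, 1 kHz, no noise."""
    trace, gt = simulate_contraction_trace(
        force_waveform,
        RhythmParams(mean_rr=1.0),
        RecordingParams(duration=10.0, sample_rate=1000.0, noise_sd=0.0,
                        seed=1),
    )
    return trace, gt


def isolated_transient(tau, baseline=0.8, amplitude=0.5, rise=0.10,
                       sample_rate=1000.0, duration=4.0, seed=0):
    """A single noiseless transient whose decay runs to the recording end."""
    wf = BeatWaveformParams(baseline=baseline, amplitude_mean=amplitude,
                            amplitude_cv=0.0, rise_duration=rise,
                            decay_tau=tau, kind="ca")
    trace, gt = simulate_contraction_trace(
        wf, RhythmParams(mean_rr=duration + 1.0),
        RecordingParams(duration=duration, sample_rate=sample_rate,
                        noise_sd=0.0, seed=seed),
    )
    return trace, gt


@pytest.fixture
def single_transient():
    return isolated_transient


def assert_within_3se(samples, target, label=""):
    samples = np.asarray(samples, dtype=float)
    se = samples.std(ddof=1) / np.sqrt(samples.size)
    assert abs(samples.mean() - target) < 3 * se, (
        f"{label}: mean {samples.mean():.6g} vs target {target:.6g} "
        f"(3 SE = {3 * se:.2g})"
    )
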