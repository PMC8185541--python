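#!/usr/bin/env python
"""Simulate the study conditions: two EHT lines (isogenic control vs
PLN-mutant-like phenotype) as contraction-trace cohorts, a Ca2+-load
series for the irregularity analysis, and caffeine SR-load protocols.

Control EHTs beat at ~81 BPM developing 0.14 mN; the disease line beats
faster (~98 BPM) at half the force with more beat-to-beat jitter.  Ca2+
transients decay with tau 0.209 s (control) vs 0.272 s (disease), both
lines sharing the same caffeine-transient amplitude (SR load unchanged).
Traces are written under results/sim/ with JSON ground-truth sidecars.
"""

from pathlib import Path

from ehtphysio import (BeatWaveformParams, CaffeineProtocolParams,
                       RecordingParams, RhythmParams, rhythm_for_ca_load,
                       simulate_ca_protocol, simulate_contraction_trace)
from ehtphysio.io import write_trace
from ehtphysio.pipeline import child_seed

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "sim"
SEED = 20260928

COHORTS = {
    "control": dict(amplitude=0.14, mean_rr=0.74074, tau=0.20939,
                    rr_sd_factor=1.0, ectopic_factor=0.3),
    "mutant": dict(amplitude=0.07, mean_rr=0.61224, tau=0.27153,
                   rr_sd_factor=2.0, ectopic_factor=1.0),
}
CA_LOADS_MM = (1.0, 1.8, 3.0)


def main() -> None:
    n_eht = 20
    for gi, (group, p) in enumerate(COHORTS.items()):
        # spontaneous contraction cohort (60 s, 1 kHz, 0.005 mN noise)
        wf = BeatWaveformParams(baseline=0.02, amplitude_mean=p["amplitude"],
                                amplitude_cv=0.10, rise_duration=0.12,
                                decay_tau=0.15)
        for i in range(n_eht):
            trace, gt = simulate_contraction_trace(
                wf, RhythmParams(mean_rr=p["mean_rr"], rr_sd=0.02),
                RecordingParams(duration=60, sample_rate=1000,
                                noise_sd=0.005,
                                seed=child_seed(SEED, gi * 1000 + i)))
            trace.metadata["group"] = group
            write_trace(OUT / "contraction" / f"{group}_{i:02d}.tsv",
                        trace, ground_truth=gt)

        # 50-s recordings across extracellular Ca2+ for the RR-scatter assay
        for ca in CA_LOADS_MM:
            rhythm = rhythm_for_ca_load(
                ca, mean_rr=p["mean_rr"],
                base_rr_sd=0.008 * p["rr_sd_factor"],
                rr_sd_per_mm=0.015 * p["rr_sd_factor"],
                ectopic_per_mm=0.05 * p["ectopic_factor"])
            for i in range(12):
                trace, gt = simulate_contraction_trace(
                    wf, rhythm,
                    RecordingParams(duration=50, sample_rate=250,
                                    noise_sd=0.005,
                                    seed=child_seed(SEED,
                                                    20_000 + gi * 5000
                                                    + int(ca * 10) * 100 + i)))
                trace.metadata.update(group=group, ca_mm=ca)
                write_trace(OUT / "ca_load" / f"{group}_ca{ca}_{i:02d}.tsv",
                            trace, ground_truth=gt)

        # caffeine protocol (paced 0.5 Hz, pacing off, one caffeine bolus);
        # both lines share factor 1.0: SR Ca2+ load is not reduced
        ca_wf = BeatWaveformParams(baseline=0.8, amplitude_mean=0.5,
                                   amplitude_cv=0.05, rise_duration=0.08,
                                   decay_tau=p["tau"], kind="ca")
        proto = CaffeineProtocolParams(paced_segment=20, pacing_rate=0.5,
                                       pacing_off_gap=10,
                                       caffeine_amplitude_factor=1.0)
        for i in range(10):
            trace, gt = simulate_ca_protocol(
                ca_wf, proto,
                RecordingParams(duration=40, sample_rate=250,
                                noise_sd=0.008,
                                seed=child_seed(SEED, 60_000 + gi * 100 + i)))
            trace.metadata["group"] = group
            write_trace(OUT / "caffeine" / f"{group}_{i:02d}.tsv",
                        trace, ground_truth=gt)

    n_files = sum(1 for _ in OUT.rglob("*.tsv"))
    print(f"wrote {n_files} trace files under {OUT}")


if __name__ == "__main__":
    main()
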