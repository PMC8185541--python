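"""End-to-end pipeline orchestration.

:func:`run_pipeline` executes one of four tasks (``simulate``, ``traces``,
``ca``, ``proteomics``) from a :class:`PipelineConfig`, writes TSV result
tables and a JSON run manifest (package version, seed, config hash) into
the output directory, and is deterministic: identical config + seed give
byte-identical outputs.

Seed fan-out: recording ``i`` of a simulated cohort uses
``child_seed(seed, i) = (seed + 1000003 * (i + 1)) % 2**31``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beats import compare_cohorts, detect_beats, summarize_trace
from .calcium import caffeine_analysis, measure_transient
from .io import read_abundance, read_trace, write_abundance, write_trace
from .proteomics import (FilterRule, differential_abundance_pipeline,
                         pca_retain)
from .synth import (BeatWaveformParams, CaffeineProtocolParams,
                    ProteomicsSimParams, RecordingParams, RhythmParams,
                    simulate_ca_protocol, simulate_contraction_trace,
                    simulate_proteomics)

logger = logging.getLogger(__name__)

TASKS = ("simulate", "traces", "ca", "proteomics")
_FLOAT_FMT = "%.10g"


def child_seed(seed: int, i: int) -> int:
    """Deterministic per-recording sub-seed (documented counter scheme)."""
    return (int(seed) + 1000003 * (i + 1)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """One pipeline invocation; round-trips through YAML unchanged."""

    task: str
    out_dir: str
    inputs: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}, got {self.task!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def _trace_paths(inputs: list[str]) -> list[Path]:
    paths: list[Path] = []
    for item in inputs:
        p = Path(item)
        if not p.exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
        if p.is_dir():
            paths.extend(sorted(q for q in p.iterdir()
                                if q.suffix in (".tsv", ".txt", ".csv")))
        else:
            paths.append(p)
    if not paths:
        raise FileNotFoundError(f"no trace files found under {inputs}")
    return paths


def _summary_row(name: str, s) -> dict:
    return {
        "recording": name,
        "group": s.metadata.get("group", ""),
        "n_beats": s.n_beats,
        "mean_force": s.mean_force,
        "frequency_bpm": s.frequency_bpm,
        "rr_scatter_idr": s.rr_scatter_idr,
        "mean_ttp_m80": s.mean_ttp_m80,
        "mean_rt80": s.mean_rt80,
        "mean_rt80_over_amplitude": s.mean_rt80_over_amplitude,
    }


def _task_simulate(cfg: PipelineConfig, out: Path) -> list[str]:
    p = dict(cfg.params)
    n_rec = int(p.pop("n_recordings", 5))
    mode = p.pop("mode", "contraction")  # contraction | caffeine | proteomics
    written = []
    if mode == "proteomics":
        sim = ProteomicsSimParams(**p.get("proteomics", {}), seed=cfg.seed)
        am, _ = simulate_proteomics(sim)
        write_abundance(am, out / "abundance.tsv", out / "groups.tsv")
        written += ["abundance.tsv", "groups.tsv"]
        return written
    wf = BeatWaveformParams(**p.get("waveform", {}))
    for i in range(n_rec):
        rec = RecordingParams(**p.get("recording", {}), seed=child_seed(cfg.seed, i))
        if mode == "caffeine":
            proto = CaffeineProtocolParams(**p.get("protocol", {}))
            trace, gt = simulate_ca_protocol(wf, proto, rec)
        else:
            rhythm = RhythmParams(**p.get("rhythm", {}))
            trace, gt = simulate_contraction_trace(wf, rhythm, rec)
        name = f"rec_{i:03d}.tsv"
        trace.metadata.setdefault("group", p.get("group", ""))
        write_trace(out / name, trace, params=p, ground_truth=gt)
        written.append(name)
    return written


def _task_traces(cfg: PipelineConfig, out: Path) -> list[str]:
    p = cfg.params
    detect_kw = dict(
        min_prominence=p.get("min_prominence"),
        min_rr=p.get("min_rr", 0.25),
        smooth_window=p.get("smooth_window", 0.0),
    )
    rows, summaries = [], {}
    for path in _trace_paths(cfg.inputs):
        trace = read_trace(path)
        beats = detect_beats(trace, **detect_kw)
        s = summarize_trace(trace, beats)
        summaries.setdefault(s.metadata.get("group", ""), []).append(s)
        rows.append(_summary_row(path.name, s))
        if s.avg_peak_normalized is not None:
            wav = pd.DataFrame({
                "t_s": (np.arange(s.avg_peak_normalized.size)
                        - s.avg_peak_normalized.size // 2) * s.avg_peak_dt,
                "absolute": s.avg_peak_absolute,
                "normalized": s.avg_peak_normalized,
            })
            _write_tsv(wav, out / f"{path.stem}_avg_peak.tsv", index=False)
    _write_tsv(pd.DataFrame(rows), out / "trace_summaries.tsv", index=False)
    written = ["trace_summaries.tsv"]
    named = {g: s for g, s in summaries.items() if g}
    if len(named) == 2:
        (ga, la), (gb, lb) = sorted(named.items())
        if len(la) >= 2 and len(lb) >= 2:
            rep = compare_cohorts(la, lb)
            rep.insert(0, "cohort_b", gb)
            rep.insert(0, "cohort_a", ga)
            _write_tsv(rep, out / "cohort_comparison.tsv")
            written.append("cohort_comparison.tsv")
    return written


def _task_ca(cfg: PipelineConfig, out: Path) -> list[str]:
    p = cfg.params
    detect_kw = dict(
        min_prominence=p.get("min_prominence"),
        min_rr=p.get("min_rr", 0.25),
        smooth_window=p.get("smooth_window", 0.0),
    )
    caffeine = p.get("protocol") == "caffeine"
    rows = []
    for path in _trace_paths(cfg.inputs):
        trace = read_trace(path, signal_kind="ca")
        if caffeine:
            res = caffeine_analysis(trace, **detect_kw)
            rows.append({
                "recording": path.name,
                "twitch_amplitude_mean": res.twitch_amplitude_mean,
                "caffeine_amplitude": res.caffeine_amplitude,
                "caffeine_ratio": res.caffeine_ratio,
                "caffeine_tau": res.caffeine_tau,
            })
        else:
            beats = detect_beats(trace, **detect_kw)
            for j, b in enumerate(beats):
                m = measure_transient(trace, b)
                rows.append({
                    "recording": path.name, "beat": j,
                    "diastolic": m.diastolic, "amplitude": m.amplitude,
                    "dt80": m.dt80, "tau": m.tau,
                    "fit_rmse": m.fit_rmse, "poor_fit": m.poor_fit,
                })
    name = "caffeine_results.tsv" if caffeine else "ca_transients.tsv"
    _write_tsv(pd.DataFrame(rows), out / name, index=False)
    return [name]


def _task_proteomics(cfg: PipelineConfig, out: Path) -> list[str]:
    if len(cfg.inputs) != 2:
        raise FileNotFoundError(
            "proteomics task needs [matrix.tsv, groups.tsv] as inputs"
        )
    am = read_abundance(cfg.inputs[0], cfg.inputs[1])
    p = cfg.params
    rule = FilterRule(**p.get("filter_rule", {}))
    res = differential_abundance_pipeline(
        am, rule=rule, k=int(p.get("knn_k", 3)),
        pseudocount=float(p.get("pseudocount", 1.0)),
    )
    _write_tsv(res.table, out / "de_results.tsv")
    kept = res.table.dropna(subset=["p_value"])
    volcano = kept[["log2_fc", "p_value", "bh_adjusted_p"]].copy()
    volcano["neg_log10_p"] = -np.log10(volcano["p_value"])
    volcano["significant"] = volcano["bh_adjusted_p"] < float(p.get("fdr", 0.05))
    _write_tsv(volcano, out / "volcano.tsv")
    from .proteomics import (filter_missing, knn_impute, log2_transform,
                             normalize_abundance)
    logged = log2_transform(
        knn_impute(filter_missing(normalize_abundance(am), rule)[0],
                   k=int(p.get("knn_k", 3))),
        pseudocount=float(p.get("pseudocount", 1.0)),
    )
    pca = pca_retain(logged, variance_threshold=float(p.get("pca_variance", 0.90)))
    scores = pca.scores.iloc[:, :3].copy()
    scores["group"] = am.groups.values
    _write_tsv(scores, out / "pca_scores.tsv")
    _write_tsv(pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(pca.variance_fractions.size)],
        "variance_fraction": pca.variance_fractions,
        "retained": [i < pca.n_retained
                     for i in range(pca.variance_fractions.size)],
    }), out / "pca_variance.tsv", index=False)
    return ["de_results.tsv", "volcano.tsv", "pca_scores.tsv",
            "pca_variance.tsv"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute one configured task; returns the manifest dict.

    Outputs: per-task TSV tables plus ``manifest.json`` recording the
    package version, the seed, the config (and its hash) and the written
    files.  Any stage error propagates with a stage-tagged message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {"simulate": _task_simulate, "traces": _task_traces,
              "ca": _task_ca, "proteomics": _task_proteomics}[config.task]
    logger.info("task=%s seed=%d out=%s", config.task, config.seed, out)
    try:
        written = runner(config, out)
    except Exception as exc:
        raise type(exc)(f"[{config.task}] {exc}") from exc
    manifest = {
        "package": "ehtphysio",
        "version": __version__,
        "task": config.task,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256": config.config_hash(),
        "outputs": sorted(written),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
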