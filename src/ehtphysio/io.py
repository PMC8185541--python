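"""Delimited-text file formats for traces and abundance matrices.

Traces are 2-column delimited text (time_s, value; tab, comma or
whitespace separated, optional header) with an optional JSON sidecar
(``<trace>.json``) carrying metadata and, for simulated data, the
generator parameters and ground truth.  Abundance matrices are TSV with
proteins as rows and samples as columns (empty cell = missing) plus a
sample-annotation TSV (sample_id, group).
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .proteomics import AbundanceMatrix
from .trace import Trace

_SPLIT = re.compile(r"[,\t;]|\s+")


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def read_trace(path, signal_kind: Optional[str] = None) -> Trace:
    """Read a 2-column (time_s, value) delimited text trace.

    The sampling step is the median time difference; any step deviating
    from it by more than 1 % is an error, as are non-monotone times and
    non-numeric cells (both reported with their line number).  Metadata
    (signal kind, protocol boundaries, ...) is taken from the JSON sidecar
    when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    times, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = [t for t in _SPLIT.split(line) if t]
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                t, v = float(tokens[0]), float(tokens[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in {tokens[:2]}"
                ) from None
            times.append(t)
            values.append(v)
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    t = np.asarray(times)
    steps = np.diff(t)
    bad = np.nonzero(steps <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: non-monotone time around line {int(bad[0]) + 2}"
        )
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 0.01 * dt:
        worst = int(np.argmax(np.abs(steps - dt)))
        raise ValueError(
            f"{path}: irregular sampling around line {worst + 2} "
            f"(step {steps[worst]:.6g} vs median {dt:.6g})"
        )
    metadata = {}
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            payload = json.load(fh)
        metadata = payload.get("metadata", {})
        if signal_kind is None:
            signal_kind = metadata.get("signal_kind")
    return Trace(dt=dt, values=np.asarray(values),
                 signal_kind=signal_kind or "force", metadata=metadata)


def write_trace(path, trace: Trace, params: Optional[dict] = None,
                ground_truth=None) -> None:
    """Write a trace as 2-column TSV plus a JSON metadata sidecar.

    Values are written with 17 significant digits so a read-back
    round-trips bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = trace.times
    with open(path, "w") as fh:
        fh.write("time_s\tvalue\n")
        for ti, vi in zip(t, trace.values):
            fh.write(f"{ti:.17g}\t{vi:.17g}\n")
    payload = {"metadata": _to_jsonable(trace.metadata),
               "dt_s": trace.dt, "signal_kind": trace.signal_kind}
    if params is not None:
        payload["params"] = _to_jsonable(params)
    if ground_truth is not None:
        payload["ground_truth"] = _to_jsonable(ground_truth)
    with open(sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_abundance(matrix_path, groups_path) -> AbundanceMatrix:
    """Read a proteins-x-samples TSV (empty cell = missing) and a
    (sample_id, group) annotation TSV."""
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    for p in (matrix_path, groups_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(groups_path, sep="\t")
    if not {"sample_id", "group"} <= set(ann.columns):
        raise ValueError(f"{groups_path}: needs columns sample_id, group")
    groups = ann.set_index("sample_id")["group"]
    missing = [c for c in data.columns if c not in groups.index]
    if missing:
        raise ValueError(f"samples without group annotation: {missing}")
    return AbundanceMatrix(data=data, groups=groups.reindex(data.columns))


def write_abundance(am: AbundanceMatrix, matrix_path, groups_path) -> None:
    matrix_path, groups_path = Path(matrix_path), Path(groups_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    am.data.to_csv(matrix_path, sep="\t", float_format="%.10g", na_rep="")
    pd.DataFrame({"sample_id": am.groups.index, "group": am.groups.values}) \
        .to_csv(groups_path, sep="\t", index=False)
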