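"""Uniformly sampled single-channel recordings.

A :class:`Trace` holds one contraction-force (mN) or Fura-2 ratio
(dimensionless) recording on a uniform time grid.  All analysis code in this
package consumes this container; file I/O lives in :mod:`ehtphysio.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SIGNAL_KINDS = ("force", "ca")


@dataclass
class Trace:
    """Uniformly sampled recording.

    Parameters
    ----------
    dt
        Sampling interval in seconds (uniform, > 0).
    values
        Signal samples; mN for ``signal_kind="force"``, dimensionless ratio
        for ``signal_kind="ca"``.
    signal_kind
        ``"force"`` or ``"ca"``.
    metadata
        Free-form recording annotations (recording id, condition,
        extracellular Ca2+ in mM, pacing protocol boundaries, ...).
    """

    dt: float
    values: np.ndarray
    signal_kind: str = "force"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples * dt)."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt
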