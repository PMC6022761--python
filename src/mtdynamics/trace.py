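"""Core length-vs-time container shared across the pipeline.

A :class:`LengthTrace` is the central in-memory object: microtubule length
(μm, including any stabilized seed segment) sampled at known times.  Traces
are produced by the simulator, by kymograph tracking, or loaded from CSV,
and consumed by every analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["LengthTrace", "GROWING", "SHRINKING"]

GROWING = 1
SHRINKING = -1


@dataclass
class LengthTrace:
    """Time-stamped microtubule length series.

    Parameters
    ----------
    times_s
        Strictly increasing sample times in seconds.
    lengths_um
        Microtubule length at each time, in micrometers (finite, >= 0).
    frame_interval_s
        Nominal sampling interval in seconds.
    condition
        Free-text condition label (e.g. genotype or tubulin treatment).
    tubulin_conc_uM
        Free-tubulin concentration for in vitro traces, if known.
    states
        Optional per-sample polymerization state (+1 growing, -1 shrinking);
        carried by simulated traces as ground truth.
    flags
        Optional per-sample boolean quality flags (e.g. frame fell entirely
        below the tracking threshold).
    """

    times_s: np.ndarray
    lengths_um: np.ndarray
    frame_interval_s: float
    condition: str = ""
    tubulin_conc_uM: Optional[float] = None
    states: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.lengths_um.shape:
            raise ValueError("times_s and lengths_um must be 1-D arrays of equal length")
        if self.times_s.size >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        if not np.all(np.isfinite(self.lengths_um)) or np.any(self.lengths_um < 0):
            raise ValueError("lengths_um must be finite and non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for name in ("states", "flags"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.times_s.shape:
                    raise ValueError(f"{name} must match times_s in shape")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    def slice(self, start_idx: int, end_idx: int) -> "LengthTrace":
        """Sub-trace over frames ``start_idx..end_idx`` inclusive."""
        sl = np.s_[start_idx : end_idx + 1]
        return replace(
            self,
            times_s=self.times_s[sl],
            lengths_um=self.lengths_um[sl],
            states=None if self.states is None else self.states[sl],
            flags=None if self.flags is None else self.flags[sl],
        )
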