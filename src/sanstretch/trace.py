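"""Uniformly sampled time-series container shared by all pipeline stages.

A :class:`Trace` holds one channel (ECG, force, or membrane potential)
on a uniform time grid in milliseconds. It is deliberately minimal: the
analysis modules only ever need the grid spacing, the sample values, and
round-tripping through two-column CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """One uniformly sampled channel.

    Parameters
    ----------
    time_ms : array of float
        Strictly increasing, uniformly spaced sample times in milliseconds.
    values : array of float
        Sample values (mV, gram-force, arbitrary ECG units, ...).
    units : str
        Free-text unit label carried through to CSV headers.
    """

    time_ms: np.ndarray
    values: np.ndarray
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_ms.ndim != 1 or self.time_ms.shape != self.values.shape:
            raise ValueError("time_ms and values must be 1-D arrays of equal length")
        if len(self.time_ms) >= 2:
            steps = np.diff(self.time_ms)
            if np.any(steps <= 0):
                raise ValueError("time_ms must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")

    @property
    def dt_ms(self) -> float:
        """Grid spacing in ms."""
        if len(self.time_ms) < 2:
            raise ValueError("trace too short to define a grid spacing")
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt_ms

    def __len__(self) -> int:
        return len(self.time_ms)

    def window(self, t_start_ms: float, t_end_ms: float) -> "Trace":
        """Sub-trace with ``t_start_ms <= t < t_end_ms``."""
        sel = (self.time_ms >= t_start_ms) & (self.time_ms < t_end_ms)
        return Trace(self.time_ms[sel], self.values[sel], units=self.units)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time_ms, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, units: str = "a.u.") -> "Trace":
        df = pd.read_csv(path)
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), units=units)
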