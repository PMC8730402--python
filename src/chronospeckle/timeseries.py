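"""Uniformly sampled time series container and CSV round-trip.

All temporal data in the package — expression time courses, sphericity
traces, FRAP recoveries, processing-rate series — flow through a single
:class:`TimeSeries` type so that the spectral machinery can treat them
uniformly.  Times are in hours for expression/imaging data and seconds
for FRAP; the container is unit-agnostic and callers keep track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]

# relative tolerance for declaring a grid uniform
_UNIFORM_RTOL = 1e-6


@dataclass(frozen=True)
class TimeSeries:
    """A (time, value) vector sampled on a strictly increasing grid.

    Parameters
    ----------
    times
        Strictly increasing sample times (hours or seconds).
    values
        Sample values, same length as ``times``.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if t.size != v.size:
            raise ValueError(f"length mismatch: {t.size} times vs {v.size} values")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def uniform_dt(self) -> float | None:
        """Sampling interval if the grid is uniform, else ``None``."""
        if len(self) < 2:
            return None
        dt = np.diff(self.times)
        dt0 = dt[0]
        if np.max(np.abs(dt - dt0)) < _UNIFORM_RTOL * abs(dt0):
            return float(dt0)
        return None

    @property
    def is_uniform(self) -> bool:
        return self.uniform_dt is not None

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.times.copy(), np.asarray(values, dtype=float))

    # ------------------------------------------------------------------ I/O
    def to_frame(self, time_col: str = "time_h", value_col: str = "value") -> pd.DataFrame:
        return pd.DataFrame({time_col: self.times, value_col: self.values})

    def to_csv(self, path, time_col: str = "time_h", value_col: str = "value") -> None:
        self.to_frame(time_col, value_col).to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, time_col: str = "time_h", value_col: str = "value"
    ) -> "TimeSeries":
        return cls(df[time_col].to_numpy(float), df[value_col].to_numpy(float))

    @classmethod
    def read_csv(cls, path, time_col: str = "time_h", value_col: str = "value") -> "TimeSeries":
        return cls.from_frame(pd.read_csv(path), time_col, value_col)
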