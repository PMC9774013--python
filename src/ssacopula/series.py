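"""Uniformly sampled univariate time series (heart rate in bpm)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    values : array-like
        Sample values (bpm for heart rate); length >= 2, all finite.
    sampling_interval : float, default 1.0
        Seconds between consecutive epochs (wearable HR streams are
        nominally 1 Hz).
    t0 : float, default 0.0
        Time stamp of the first epoch, in seconds.
    """

    values: np.ndarray
    sampling_interval: float = 1.0
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {arr.shape}")
        if arr.size < 2:
            raise ValueError(f"series must have length >= 2, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series contains non-finite values")
        if not self.sampling_interval > 0:
            raise ValueError(f"sampling_interval must be > 0, got {self.sampling_interval}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __getitem__(self, key):
        if isinstance(key, slice):
            start = key.start or 0
            if start < 0:
                start += len(self)
            return TimeSeries(
                self.values[key],
                sampling_interval=self.sampling_interval,
                t0=self.t0 + start * self.sampling_interval,
            )
        return float(self.values[key])

    @property
    def times(self) -> np.ndarray:
        """Epoch time stamps in seconds."""
        return self.t0 + self.sampling_interval * np.arange(len(self))
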