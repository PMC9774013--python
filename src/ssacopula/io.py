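"""CSV and configuration I/O for heart-rate series.

The on-disk series format is a two-column CSV with a header
(``t_seconds, hr_bpm``): explicit time stamps in seconds and HR values in
bpm.  Reading validates monotone time and uniform sampling and reports the
offending line on failure (line numbers are 1-based and include the header).
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .model import PredictorConfig
from .series import TimeSeries

__all__ = ["ParseError", "read_series", "write_series", "load_config", "save_config"]

#: relative tolerance on sampling-interval uniformity
_UNIFORM_TOL = 1e-6


class ParseError(ValueError):
    """A series file failed validation; the message names the line."""


def read_series(path) -> TimeSeries:
    """Read a two-column (time seconds, HR bpm) CSV into a TimeSeries."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (time, value), got {frame.shape[1]}")
    t_raw, v_raw = frame.iloc[:, 0], frame.iloc[:, 1]
    for name, col in (("time", t_raw), ("value", v_raw)):
        coerced = pd.to_numeric(col, errors="coerce")
        bad = coerced.isna() & col.notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}, line {line}: non-numeric {name} cell {col[bad.idxmax()]!r}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ParseError(f"{path}, line {line}: missing {name} cell")
    t = pd.to_numeric(t_raw).to_numpy(dtype=float)
    v = pd.to_numeric(v_raw).to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 rows, got {t.size}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.argmax(dt <= 0)) + 3  # second row of the offending pair
        kind = "duplicated" if dt[np.argmax(dt <= 0)] == 0 else "non-monotone"
        raise ParseError(f"{path}, line {line}: {kind} timestamp {t[np.argmax(dt <= 0) + 1]!r}")
    step = float(np.median(dt))
    irregular = np.abs(dt - step) > _UNIFORM_TOL * max(step, 1.0)
    if irregular.any():
        line = int(np.argmax(irregular)) + 3
        raise ParseError(
            f"{path}, line {line}: irregular sampling (gap {dt[np.argmax(irregular)]:g} s "
            f"vs nominal {step:g} s)"
        )
    return TimeSeries(v, sampling_interval=step, t0=float(t[0]))


def write_series(series: TimeSeries, path) -> None:
    """Write a TimeSeries as a ``t_seconds, hr_bpm`` CSV at full precision."""
    frame = pd.DataFrame({"t_seconds": series.times, "hr_bpm": series.values})
    frame.to_csv(path, index=False)


def load_config(path) -> PredictorConfig:
    """Load a predictor configuration from a flat YAML mapping."""
    data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    known = set(PredictorConfig().to_dict())
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    return PredictorConfig.from_dict(data)


def save_config(config: PredictorConfig, path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
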