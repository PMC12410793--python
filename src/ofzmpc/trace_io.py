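"""Closed-loop trace CSV I/O.

Single flat dialect: comma-separated, UTF-8, header row, times in minutes.
Round trips are lossless to well below 1e-9 (floats are written with 17
significant digits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .virtual_trial import TRACE_COLUMNS, ClosedLoopTrace

__all__ = ["read_trace", "write_trace", "TraceFormatError"]

_FLOAT_COLUMNS = [
    "time_min",
    "glucose_true",
    "cgm",
    "insulin_U",
    "meal_g",
    "projection_5min",
    "x2",
    "x3",
    "x4",
    "x5",
    "d_hat",
]


class TraceFormatError(ValueError):
    pass


def write_trace(trace: ClosedLoopTrace, path) -> None:
    frame = trace.frame.copy()
    frame["cgm_missing"] = frame["cgm_missing"].astype(bool)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_trace(path) -> ClosedLoopTrace:
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TraceFormatError(f"malformed trace CSV {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing required columns {missing}")
    for i, col in enumerate(_FLOAT_COLUMNS):
        try:
            frame[col] = frame[col].astype(float)
        except (TypeError, ValueError) as exc:
            bad = _first_bad_row(frame[col])
            raise TraceFormatError(
                f"{path}: column {col!r} is not numeric "
                f"(first bad value at data line {bad + 2})"
            ) from exc
    frame["cgm_missing"] = frame["cgm_missing"].astype(bool)
    frame["solver_status"] = frame["solver_status"].astype(str)
    return ClosedLoopTrace(frame=frame[TRACE_COLUMNS])


def _first_bad_row(series: pd.Series) -> int:
    for i, v in enumerate(series):
        try:
            float(v)
        except (TypeError, ValueError):
            return i
    return 0


def traces_allclose(a: ClosedLoopTrace, b: ClosedLoopTrace, tol: float = 1e-9) -> bool:
    if len(a) != len(b):
        return False
    for col in _FLOAT_COLUMNS:
        x = a.frame[col].to_numpy(dtype=float)
        y = b.frame[col].to_numpy(dtype=float)
        if not np.array_equal(np.isfinite(x), np.isfinite(y)):
            return False
        if not np.allclose(x[np.isfinite(x)], y[np.isfinite(y)], atol=tol, rtol=0):
            return False
    return (
        a.frame["cgm_missing"].tolist() == b.frame["cgm_missing"].tolist()
        and a.frame["solver_status"].tolist() == b.frame["solver_status"].tolist()
    )
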