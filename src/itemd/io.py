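"""Readers and writers for signals, IMFs and reports.

CSV dialect: comma-delimited, '.' decimal, optional single header row.
Sampling rates are never inferred from files; callers supply them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sifting import IMFSet, Signal

__all__ = ["read_signal", "write_signal", "write_imfs", "read_imfs", "write_report"]


class DataFormatError(ValueError):
    """Malformed input data (bad token, NaN, wrong shape)."""


def _parse_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, sep=",")
    except Exception as exc:
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    had_header = False
    try:
        df = raw.astype(float)
    except (TypeError, ValueError):
        # retry treating the first row as a single header line
        try:
            df = raw.iloc[1:].reset_index(drop=True).astype(float)
            had_header = True
        except (TypeError, ValueError) as exc:
            raise DataFormatError(
                f"{path}: non-numeric value in data rows ({exc})"
            ) from exc
    bad = df.index[~np.isfinite(df).all(axis=1)]
    if len(bad):
        line = int(bad[0]) + 1 + (1 if had_header else 0)
        raise DataFormatError(f"{path}: non-finite value at line {line}")
    return df


def read_signal(path, fs: float, column: int = 0) -> Signal:
    """Read one channel of a delimited text file as a Signal."""
    df = _parse_csv(path)
    if not 0 <= column < df.shape[1]:
        raise DataFormatError(f"{path}: no column {column} (file has {df.shape[1]})")
    return Signal(df.iloc[:, column].to_numpy(), fs)


def write_signal(samples: np.ndarray, path) -> None:
    pd.DataFrame({"signal": np.asarray(samples, dtype=float)}).to_csv(path, index=False)


def write_imfs(imfs: IMFSet, path) -> None:
    """Write IMFs and residual as CSV columns imf_1..imf_K, residual."""
    data = {f"imf_{i + 1}": imfs.imf(i) for i in range(imfs.n_imfs)}
    data["residual"] = imfs.residual
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.15g")


def read_imfs(path, fs: float) -> IMFSet:
    df = _parse_csv(path)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected >= 2 columns (imfs + residual)")
    arr = df.to_numpy()
    return IMFSet(arr[:, :-1], arr[:, -1], fs)


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(obj: dict, path) -> None:
    """Write a JSON report, converting numpy scalars/arrays transparently."""
    Path(path).write_text(json.dumps(_to_jsonable(obj), indent=2) + "\n")
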