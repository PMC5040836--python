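"""Delimited-text reading and writing of multichannel signals.

The canonical on-disk format stores channels as columns, one sample per
row, comma- or tab-separated, with an optional header row of channel
names and an optional ``# sampling_rate=<Hz>`` comment line.  Values
round-trip at full double precision.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import MultichannelSignal

_DELIMITERS = {"comma": ",", "tab": "\t"}


def _sep(delimiter: str) -> str:
    try:
        return _DELIMITERS[delimiter]
    except KeyError:
        raise ValueError(f"delimiter must be 'comma' or 'tab', got {delimiter!r}") from None


def write_signal(
    signal: MultichannelSignal,
    path: str | Path,
    delimiter: str = "comma",
    header: bool = True,
) -> None:
    """Write a signal as delimited text, channels as columns."""
    data = signal.data
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite values")
    sep = _sep(delimiter)
    lines = []
    if signal.sampling_rate is not None:
        lines.append(f"# sampling_rate={signal.sampling_rate!r}")
    names = signal.channel_names or [f"ch{i + 1}" for i in range(signal.n_channels)]
    if header:
        lines.append(sep.join(names))
    for t in range(signal.n_samples):
        lines.append(sep.join(format(v, ".17g") for v in data[:, t]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_signal(path: str | Path, delimiter: str | None = None) -> MultichannelSignal:
    """Read a delimited-text signal file written by :func:`write_signal`.

    The delimiter is sniffed from the first data line when not given.
    Non-numeric cells are reported with their 1-based (row, column)
    position; ragged rows and empty files are rejected.
    """
    text = Path(path).read_text()
    sampling_rate = None
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if "sampling_rate=" in stripped:
                sampling_rate = float(stripped.split("sampling_rate=")[1].strip())
            continue
        body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: file contains no data")
    if delimiter is None:
        sep = "\t" if "\t" in body_lines[0] else ","
    else:
        sep = _sep(delimiter)

    def _is_numeric_row(line: str) -> bool:
        for cell in line.split(sep):
            try:
                float(cell)
            except ValueError:
                return False
        return True

    channel_names = None
    if not _is_numeric_row(body_lines[0]):
        channel_names = [c.strip() for c in body_lines[0].split(sep)]
        body_lines = body_lines[1:]
        if not body_lines:
            raise ValueError(f"{path}: header but no data rows")

    df = pd.read_csv(
        _io.StringIO("\n".join(body_lines)), sep=sep, header=None,
        float_precision="round_trip",
    )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {bad[0] + 1}, column {bad[1] + 1}"
        )
    if channel_names is not None and len(channel_names) != numeric.shape[1]:
        raise ValueError(f"{path}: header names {len(channel_names)} columns, data has {numeric.shape[1]}")
    return MultichannelSignal(
        data=numeric.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_names=channel_names,
    )


def write_peaks(indices: np.ndarray, path: str | Path) -> None:
    """Write peak sample indices as single-column integer text."""
    Path(path).write_text("\n".join(str(int(i)) for i in np.asarray(indices).ravel()) + "\n")


def read_peaks(path: str | Path) -> np.ndarray:
    """Read peak indices written by :func:`write_peaks`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray([int(ln) for ln in lines], dtype=int)
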