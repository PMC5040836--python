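"""Lightweight containers for multichannel time-series signals.

All signals are stored as 2-D :class:`numpy.ndarray` with shape
``(n_channels, n_samples)``; single signals ("rows") are 1-D arrays of
length ``n_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def standardize(row: np.ndarray) -> np.ndarray:
    """Return ``row`` shifted to zero mean and scaled to unit variance.

    Variance uses the ``1/T`` (population) convention throughout the
    package so that whitening, closeness and moment estimates agree.

    Raises
    ------
    ValueError
        If the input is constant (zero variance) or non-finite.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1:
        raise ValueError(f"expected a 1-D signal row, got shape {row.shape}")
    if not np.all(np.isfinite(row)):
        raise ValueError("signal contains non-finite values")
    centered = row - row.mean()
    std = np.sqrt(np.mean(centered**2))
    if std == 0.0:
        raise ValueError("cannot standardize a constant signal")
    return centered / std


@dataclass
class MultichannelSignal:
    """A ``channels x samples`` real matrix with an optional sampling rate."""

    data: np.ndarray
    sampling_rate: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float | None:
        if self.sampling_rate is None:
            return None
        return self.n_samples / self.sampling_rate


@dataclass
class SourceSet:
    """Independent source signals plus their kind labels.

    Every row is standardized (zero mean, unit variance); ``labels``
    name the source kinds in row order, e.g. ``powerline``,
    ``gaussian_noise``, ``fecg``, ``mecg``.
    """

    signals: MultichannelSignal
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.signals.n_channels:
            raise ValueError("one label per source row required")
        data = self.signals.data
        if not np.all(np.isfinite(data)):
            raise ValueError("sources contain non-finite values")
        means = data.mean(axis=1)
        variances = data.var(axis=1)
        if np.any(np.abs(means) > 1e-10) or np.any(np.abs(variances - 1) > 1e-10):
            raise ValueError("every source row must be standardized")

    @property
    def sampling_rate(self) -> float | None:
        return self.signals.sampling_rate

    def row(self, label: str) -> np.ndarray:
        """Return the (first) source row carrying ``label``."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no source labelled {label!r}; have {self.labels}") from None
        return self.signals.data[idx]

    def index_of(self, label: str) -> int:
        return self.labels.index(label)
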