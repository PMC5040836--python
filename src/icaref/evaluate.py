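"""Extraction-quality metrics for blind source extraction.

When the mixing matrix A and the whitening matrix B are known (synthetic
runs), the composition ``p = w^T B A`` — the *global system vector* —
tells exactly which mixture of the true sources the extracted signal
is.  Perfect extraction gives a rescaled one-hot p; the individual
performance index (IPI) measures the relative leakage into the other
sources.  On real data A is unknown, so quality is assessed instead by
waveform agreement between independently obtained extractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import SourceSet


@dataclass
class GlobalVector:
    """The global system vector p = w^T B A and its dominant source."""

    p: np.ndarray
    dominant_index: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float).ravel()
        if np.max(np.abs(self.p)) == 0:
            raise ValueError("global vector is all zero")
        if self.dominant_index != int(np.argmax(np.abs(self.p))):
            raise ValueError("dominant_index does not match argmax |p|")


def global_vector(w: np.ndarray, B: np.ndarray, A: np.ndarray) -> GlobalVector:
    """Compose separating vector, whitening and mixing into p = w^T B A."""
    w = np.asarray(w, dtype=float).ravel()
    B = np.atleast_2d(np.asarray(B, dtype=float))
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if w.size != B.shape[0] or B.shape[1] != A.shape[0]:
        raise ValueError(
            f"shape mismatch: w has {w.size} entries, B is {B.shape}, A is {A.shape}"
        )
    p = w @ B @ A
    return GlobalVector(p=p, dominant_index=int(np.argmax(np.abs(p))))


def ipi(p: GlobalVector | np.ndarray) -> float:
    """Individual performance index ``sum_i |p_i| / max_j |p_j| - 1``.

    Nonnegative, invariant to rescaling of p, and zero if and only if p
    is a rescaled canonical basis vector (perfect extraction up to
    scale and sign).
    """
    arr = p.p if isinstance(p, GlobalVector) else np.asarray(p, dtype=float).ravel()
    amax = np.max(np.abs(arr))
    if amax == 0:
        raise ValueError("IPI undefined for an all-zero global vector")
    return float(np.sum(np.abs(arr)) / amax - 1.0)


def match_correlation(y: np.ndarray, sources: SourceSet) -> tuple[int, float]:
    """Best |Pearson correlation| between y and each true source."""
    y = np.asarray(y, dtype=float).ravel()
    s = sources.signals.data
    if y.size != s.shape[1]:
        raise ValueError("extracted signal and sources have different lengths")
    yc = y - y.mean()
    denom = np.sqrt(np.sum(yc**2))
    if denom == 0:
        raise ValueError("cannot correlate a constant extracted signal")
    # Source rows are standardized, so their centered norm is sqrt(T).
    corrs = np.abs(s @ yc) / (denom * np.sqrt(s.shape[1]))
    best = int(np.argmax(corrs))
    return best, float(corrs[best])


def waveform_agreement(y1: np.ndarray, y2: np.ndarray) -> float:
    """|Pearson correlation| between two extractions of the same source.

    The real-data stand-in for IPI: with the true mixing unknown, two
    methods that agree almost perfectly (|corr| near 1) have extracted
    the same waveform.
    """
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    if y1.size != y2.size:
        raise ValueError("signals have different lengths")
    c1 = y1 - y1.mean()
    c2 = y2 - y2.mean()
    denom = np.linalg.norm(c1) * np.linalg.norm(c2)
    if denom == 0:
        raise ValueError("cannot correlate a constant signal")
    return float(abs(np.dot(c1, c2)) / denom)
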