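"""Centering and whitening of observed multichannel signals.

Whitening transforms the observations so their sample covariance is the
identity.  The constrained solver exploits this twice: the covariance
inverse in the Newton update becomes the identity, and any unit-norm
separating vector automatically yields a unit-variance output, so the
unit-variance equality constraint can be dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import MultichannelSignal


@dataclass
class WhiteningResult:
    """Whitened data together with the transform that produced it.

    ``whitened.data == whitening_matrix @ (x - channel_means)`` and the
    sample covariance (1/T convention) of the whitened rows is the
    identity.
    """

    whitened: MultichannelSignal
    whitening_matrix: np.ndarray
    channel_means: np.ndarray
    eigenvalues: np.ndarray


def center(x: MultichannelSignal) -> tuple[MultichannelSignal, np.ndarray]:
    """Remove each channel's mean; returns the means for invertibility."""
    data = x.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    if not np.all(np.isfinite(data)):
        raise ValueError("input contains non-finite values")
    means = data.mean(axis=1)
    centered = MultichannelSignal(
        data=data - means[:, None],
        sampling_rate=x.sampling_rate,
        channel_names=x.channel_names,
    )
    return centered, means


def whiten(x: MultichannelSignal, eigenvalue_floor: float | None = None) -> WhiteningResult:
    """Whiten centered data via eigendecomposition of the covariance.

    With covariance ``C = E D E^T`` the whitening matrix is
    ``B = D^{-1/2} E^T``.  Eigenvector signs are fixed so each vector's
    largest-magnitude component is positive, making the transform
    deterministic.  Covariance uses the ``1/T`` divisor.

    Parameters
    ----------
    x
        Centered observations, more samples than channels.
    eigenvalue_floor
        Smallest admissible covariance eigenvalue; defaults to
        ``1e-10`` times the largest eigenvalue.  A smaller eigenvalue
        indicates (near-)rank deficiency and is rejected rather than
        silently inverted.
    """
    data = x.data
    n, T = data.shape
    if T <= n:
        raise ValueError(f"need more samples ({T}) than channels ({n}) to whiten")
    if np.max(np.abs(data.mean(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(data))):
        raise ValueError("whiten expects centered input; call center() first")
    cov = data @ data.T / T
    eigvals, eigvecs = np.linalg.eigh(cov)
    floor = eigenvalue_floor if eigenvalue_floor is not None else 1e-10 * eigvals[-1]
    if eigvals[0] < floor:
        bad = int(np.argmin(eigvals))
        raise ValueError(
            f"covariance is rank deficient: eigenvalue {eigvals[0]:.3e} of "
            f"dimension {bad} is below the floor {floor:.3e}"
        )
    # Deterministic sign: largest-magnitude component of each eigenvector positive.
    for j in range(n):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    B = (eigvecs / np.sqrt(eigvals)).T
    whitened = MultichannelSignal(
        data=B @ data,
        sampling_rate=x.sampling_rate,
        channel_names=x.channel_names,
    )
    return WhiteningResult(
        whitened=whitened,
        whitening_matrix=B,
        channel_means=np.zeros(n),
        eigenvalues=eigvals,
    )


def center_and_whiten(x: MultichannelSignal, eigenvalue_floor: float | None = None) -> WhiteningResult:
    """Convenience composition of :func:`center` and :func:`whiten`."""
    centered, means = center(x)
    result = whiten(centered, eigenvalue_floor)
    result.channel_means = means
    return result
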