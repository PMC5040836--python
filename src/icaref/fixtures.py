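"""Deterministic on-disk fixtures for tests and worked examples."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io as sio
from . import synth
from .reference import build_sign_reference
from .signals import MultichannelSignal, SourceSet, standardize


def two_source_toy(seed: int, n_samples: int = 2000) -> SourceSet:
    """A unit-variance Laplacian plus an independent Gaussian.

    The minimal extraction problem: one super-Gaussian target and one
    Gaussian distractor, identity-mixed.
    """
    rng = np.random.default_rng(seed)
    laplacian = standardize(rng.laplace(size=n_samples))
    gaussian = standardize(rng.standard_normal(n_samples))
    return SourceSet(
        signals=MultichannelSignal(np.vstack([laplacian, gaussian]), sampling_rate=None),
        labels=["laplacian", "gaussian"],
    )


def abdominal_like(seed: int, n_samples: int = 2500, sampling_rate: float = 250.0) -> MultichannelSignal:
    """A single abdominal-style channel: maternal ECG + 0.3 x fetal ECG.

    Mimics the structure of a cutaneous abdominal lead (strong slow
    maternal beats with weak fast fetal beats in between), for
    exercising the peak-based reference builders.
    """
    ss = np.random.SeedSequence(seed)
    fseed, mseed = [int(s) % (2**31) for s in ss.generate_state(2)]
    fecg = synth.generate_ecg(140, sampling_rate, n_samples, synth.EcgMorphology.fetal(), seed=fseed)
    mecg = synth.generate_ecg(80, sampling_rate, n_samples, synth.EcgMorphology.maternal(), seed=mseed)
    return MultichannelSignal(
        data=(mecg + 0.3 * fecg)[None, :],
        sampling_rate=sampling_rate,
        channel_names=["abdominal"],
    )


def make_fixture(name: str, seed: int, out_dir: str | Path, delimiter: str = "comma") -> dict[str, Path]:
    """Write a named fixture to ``out_dir``; deterministic per seed.

    ``benchmark_artificial`` emits the four standard sources, their
    mixture under the fixed 4x4 matrix, and sign references for the
    fetal and maternal ECG.  ``two_source_toy`` emits the
    Laplacian/Gaussian pair identity-mixed.  ``abdominal_like`` emits a
    single composite abdominal-style channel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(key: str, signal: MultichannelSignal) -> None:
        path = out_dir / f"{key}.csv"
        sio.write_signal(signal, path, delimiter=delimiter)
        written[key] = path

    if name == "benchmark_artificial":
        sources = synth.benchmark_sources(seed)
        spec = synth.benchmark_mixing_matrix()
        mixture = synth.mix(sources, spec)
        _write("sources", sources.signals)
        _write("mixture", mixture)
        _write("mixing", MultichannelSignal(spec.matrix))
        for label in ("fecg", "mecg"):
            ref = build_sign_reference(sources.row(label))
            _write(
                f"reference_{label}",
                MultichannelSignal(ref.values[None, :], sampling_rate=sources.sampling_rate),
            )
    elif name == "two_source_toy":
        sources = two_source_toy(seed)
        _write("sources", sources.signals)
        _write("mixture", sources.signals)  # identity mixing
        ref = build_sign_reference(sources.row("laplacian"))
        _write("reference_laplacian", MultichannelSignal(ref.values[None, :]))
    elif name == "abdominal_like":
        _write("abdominal", abdominal_like(seed))
    else:
        raise ValueError(
            f"unknown fixture {name!r}; expected benchmark_artificial, "
            "two_source_toy or abdominal_like"
        )
    return written
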