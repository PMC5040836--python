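"""Synthetic source generation for ECG blind-source-extraction experiments.

The artificial benchmark mixes four independent sources: a 50 Hz
power-line sinusoid (sub-Gaussian), white Gaussian noise, and two
quasi-periodic ECG waveforms — fetal (fast, weak) and maternal (slow,
strong) — both strongly super-Gaussian because of their narrow QRS
complexes.  A fixed 4x4 mixing matrix (the one printed for the
benchmark experiment) produces the observed channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import MultichannelSignal, SourceSet, standardize

DEFAULT_SAMPLING_RATE = 500.0
DEFAULT_N_SAMPLES = 5000
DEFAULT_JITTER = 0.02

#: Entries of the benchmark 4x4 mixing matrix, row-major.
_BENCHMARK_MIXING = np.array(
    [
        [0.8925, 0.0570, 0.5044, 0.9153],
        [0.0169, 0.0590, 0.4364, 0.4911],
        [0.5165, 0.4735, 0.8193, 0.7484],
        [0.0418, 0.3840, 0.4448, 0.3421],
    ]
)


@dataclass
class MixingSpec:
    """An ``n x m`` mixing matrix A for the linear model x = A s."""

    matrix: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        smallest_sv = np.linalg.svd(self.matrix, compute_uv=False)[-1]
        if smallest_sv <= 1e-8:
            raise ValueError(
                f"mixing matrix is rank deficient (smallest singular value {smallest_sv:.3e})"
            )


@dataclass
class WaveKernel:
    """One Gaussian-shaped ECG wave: amplitude, width and center offset.

    ``center_s`` is the wave center relative to the R peak, and
    ``width_s`` the Gaussian standard deviation, both in seconds at the
    nominal 75 beat/min cycle; they are rescaled in proportion to the
    actual beat interval.
    """

    amplitude: float
    width_s: float
    center_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("wave width must be positive")


@dataclass
class EcgMorphology:
    """Per-wave (P, Q, R, S, T) kernels plus a global amplitude scale."""

    waves: dict[str, WaveKernel] = field(default_factory=dict)
    scale: float = 1.0

    @classmethod
    def maternal(cls) -> "EcgMorphology":
        return cls(
            waves={
                "P": WaveKernel(0.12, 0.025, -0.20),
                "Q": WaveKernel(-0.12, 0.010, -0.035),
                "R": WaveKernel(1.00, 0.011, 0.0),
                "S": WaveKernel(-0.18, 0.010, 0.035),
                "T": WaveKernel(0.25, 0.045, 0.28),
            },
            scale=1.0,
        )

    @classmethod
    def fetal(cls) -> "EcgMorphology":
        # Weaker and narrower than the maternal complex; the 0.3 scale
        # mirrors the amplitude ratio typically seen on abdominal leads.
        return cls(
            waves={
                "P": WaveKernel(0.10, 0.020, -0.14),
                "Q": WaveKernel(-0.10, 0.008, -0.025),
                "R": WaveKernel(1.00, 0.008, 0.0),
                "S": WaveKernel(-0.15, 0.008, 0.025),
                "T": WaveKernel(0.20, 0.035, 0.20),
            },
            scale=0.3,
        )


def generate_powerline(
    frequency_hz: float,
    sampling_rate: float,
    n_samples: int,
    phase: float = 0.0,
) -> np.ndarray:
    """Unit-variance sinusoid, e.g. 50 Hz power-line interference.

    The amplitude is ``sqrt(2)`` so the population variance is exactly
    one; over whole periods the sample variance is one as well.  A
    sinusoid has fourth moment 1.5, i.e. it is sub-Gaussian.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < frequency_hz < sampling_rate / 2:
        raise ValueError(
            f"frequency {frequency_hz} Hz must lie strictly between 0 and the "
            f"Nyquist frequency {sampling_rate / 2} Hz"
        )
    t = np.arange(n_samples) / sampling_rate
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * frequency_hz * t + phase)


def generate_gaussian_noise(n_samples: int, seed: int) -> np.ndarray:
    """Standardized white Gaussian noise; identical output per seed."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    return standardize(rng.standard_normal(n_samples))


def ecg_beat_times(
    beat_rate_bpm: float,
    duration_s: float,
    jitter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """R-peak times (seconds) with Gaussian beat-to-beat interval jitter.

    ``jitter`` is the interval standard deviation as a fraction of the
    mean interval; 0 yields an exactly periodic train.
    """
    mean_rr = 60.0 / beat_rate_bpm
    times = []
    # Start half a beat in so the first complex is fully on-record.
    t = 0.5 * mean_rr
    while t < duration_s + mean_rr:
        times.append(t)
        rr = mean_rr * (1.0 + jitter * rng.standard_normal()) if jitter > 0 else mean_rr
        t += max(rr, 0.2 * mean_rr)
    return np.asarray(times)


def generate_ecg(
    beat_rate_bpm: float,
    sampling_rate: float,
    n_samples: int,
    morphology: EcgMorphology | None = None,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    return_beat_times: bool = False,
):
    """Quasi-periodic synthetic ECG as a sum of Gaussian wave kernels.

    Each cardiac cycle places five Gaussian bumps (P, Q, R, S, T) around
    the R-peak time; widths and offsets scale with the beat interval so
    fetal (fast) and maternal (slow) traces keep a plausible shape.  The
    output is standardized to unit variance and, thanks to the narrow
    high R peak, has fourth moment well above 3 (super-Gaussian).

    When ``return_beat_times`` is set, the ground-truth R-peak times in
    seconds are returned alongside the signal.
    """
    if not 30 <= beat_rate_bpm <= 240:
        raise ValueError("beat rate must lie in [30, 240] bpm")
    if morphology is None:
        morphology = EcgMorphology.maternal()
    for name, wave in morphology.waves.items():
        if wave.width_s <= 0:
            raise ValueError(f"wave {name} has non-positive width")
    rng = np.random.default_rng(seed)
    duration_s = n_samples / sampling_rate
    beats = ecg_beat_times(beat_rate_bpm, duration_s, jitter, rng)
    t = np.arange(n_samples) / sampling_rate
    signal = np.zeros(n_samples)
    # Morphology timings are specified at a 75 bpm (0.8 s) cycle.
    stretch = (60.0 / beat_rate_bpm) / 0.8
    for beat_t in beats:
        for wave in morphology.waves.values():
            center = beat_t + wave.center_s * stretch
            width = wave.width_s * stretch
            lo = np.searchsorted(t, center - 6 * width)
            hi = np.searchsorted(t, center + 6 * width)
            if lo >= hi:
                continue
            signal[lo:hi] += morphology.scale * wave.amplitude * np.exp(
                -0.5 * ((t[lo:hi] - center) / width) ** 2
            )
    out = standardize(signal)
    if return_beat_times:
        return out, beats[beats < duration_s]
    return out


def benchmark_mixing_matrix() -> MixingSpec:
    """The fixed 4x4 mixing matrix of the artificial benchmark."""
    return MixingSpec(matrix=_BENCHMARK_MIXING.copy())


def random_mixing_matrix(n: int, m: int, seed: int) -> MixingSpec:
    """A uniformly drawn ``n x m`` mixing matrix (entries in [0, 1])."""
    rng = np.random.default_rng(seed)
    return MixingSpec(matrix=rng.uniform(0.0, 1.0, size=(n, m)), seed=seed)


def mix(sources: SourceSet, spec: MixingSpec) -> MultichannelSignal:
    """Apply the linear mixing model x = A s (no additive noise)."""
    s = sources.signals.data
    if spec.matrix.shape[1] != s.shape[0]:
        raise ValueError(
            f"mixing matrix has {spec.matrix.shape[1]} columns but there are "
            f"{s.shape[0]} sources"
        )
    return MultichannelSignal(
        data=spec.matrix @ s,
        sampling_rate=sources.signals.sampling_rate,
    )


def benchmark_sources(
    seed: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    jitter: float = DEFAULT_JITTER,
    powerline_hz: float = 50.0,
    powerline_phase: float = 0.0,
    fetal_bpm: float = 140.0,
    maternal_bpm: float = 80.0,
    return_beat_times: bool = False,
):
    """The four benchmark sources: powerline, noise, FECG, MECG.

    Rows are ordered (powerline, gaussian_noise, fecg, mecg) and each is
    standardized.  Sub-seeds for the stochastic sources are derived from
    ``seed`` so a single integer reproduces the whole set.
    """
    ss = np.random.SeedSequence(seed)
    noise_seed, fecg_seed, mecg_seed = [int(s) % (2**31) for s in ss.generate_state(3)]
    powerline = standardize(
        generate_powerline(powerline_hz, sampling_rate, n_samples, powerline_phase)
    )
    noise = generate_gaussian_noise(n_samples, noise_seed)
    fecg, fetal_beats = generate_ecg(
        fetal_bpm, sampling_rate, n_samples, EcgMorphology.fetal(),
        seed=fecg_seed, jitter=jitter, return_beat_times=True,
    )
    mecg, maternal_beats = generate_ecg(
        maternal_bpm, sampling_rate, n_samples, EcgMorphology.maternal(),
        seed=mecg_seed, jitter=jitter, return_beat_times=True,
    )
    sources = SourceSet(
        signals=MultichannelSignal(
            data=np.vstack([powerline, noise, fecg, mecg]),
            sampling_rate=sampling_rate,
            channel_names=["powerline", "gaussian_noise", "fecg", "mecg"],
        ),
        labels=["powerline", "gaussian_noise", "fecg", "mecg"],
    )
    if return_beat_times:
        return sources, {"fecg": fetal_beats, "mecg": maternal_beats}
    return sources
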