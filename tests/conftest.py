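import numpy as np
import pytest

from icaref import benchmark_mixing_matrix, benchmark_sources, mix
from icaref.preprocess import center_and_whiten


@pytest.fixture(scope="session")
def benchmark_case():
    """One seeded four-source benchmark mixture with its ground truth."""
    sources, beats = benchmark_sources(7, return_beat_times=True)
    spec = benchmark_mixing_matrix()
    mixture = mix(sources, spec)
    return {"sources": sources, "beats": beats, "spec": spec, "mixture": mixture}


@pytest.fixture(scope="session")
def whitened_benchmark(benchmark_case):
    return center_and_whiten(benchmark_case["mixture"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
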