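import numpy as np
import pytest

import rhythmfit as rf


@pytest.fixture(scope="session")
def benchmark():
    """One seeded benchmark suite shared across tests (independent replicates)."""
    return rf.generate_benchmark_suite(42)


@pytest.fixture(scope="session")
def benchmark_individuals():
    """The benchmark suite with replicates tagged as individuals."""
    return rf.generate_benchmark_suite(42, dependence="per_individual")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def noiseless_cosine(period=24.0, mesor=0.0, amplitude=1.0, acrophase=0.0,
                     span=48.0, step=2.0):
    """Deterministic single-harmonic series (helper, not a fixture)."""
    t = np.arange(0, span + step / 2, step)
    y = mesor + amplitude * np.cos(2 * np.pi * t / period + acrophase)
    return t, y
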