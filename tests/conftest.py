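import random

import pytest

from srnascreen.energy import EnergyModel
from srnascreen.synth import BenchmarkSpec, make_benchmark


@pytest.fixture(scope="session")
def model():
    return EnergyModel.default()


@pytest.fixture(scope="session")
def default_benchmark():
    """Noise-free default benchmark (the canonical study conditions)."""
    return make_benchmark(BenchmarkSpec(noise_sigma=0.0, rng_seed=0))


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))
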