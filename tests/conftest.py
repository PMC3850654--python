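import numpy as np
import pytest

from rsplis import EmissionMixture, RegionHMM


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_comp_model():
    """Two-state HMM whose non-null emission is a single N(2, 1)."""
    return RegionHMM.from_rates(0.05, 0.3, EmissionMixture([1.0], [2.0], [1.0]))


@pytest.fixture
def mix_model():
    """Two-state HMM with a two-component non-null mixture."""
    return RegionHMM.from_rates(
        0.02, 0.20, EmissionMixture([0.1, 0.9], [1.0, 3.0], [1.0, 1.0])
    )


def random_model(rng: np.random.Generator, m: int = 2) -> RegionHMM:
    a01 = rng.uniform(0.02, 0.5)
    a10 = rng.uniform(0.05, 0.8)
    xi = rng.dirichlet(np.ones(m))
    mu = rng.uniform(0.5, 4.0, size=m)
    sigma = rng.uniform(0.5, 2.0, size=m)
    return RegionHMM.from_rates(a01, a10, EmissionMixture(xi, mu, sigma))
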