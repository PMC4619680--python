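import numpy as np
import pytest

from etmap.adaptsim import make_structured_population


@pytest.fixture(scope="session")
def small_population():
    """Small structured population shared by slow-ish tests."""
    return make_structured_population(
        n_per_pop=(40, 40, 20, 20), m_snps=800, divergence=0.4, seed=42
    )


@pytest.fixture(scope="session")
def main_population():
    """Full-size population of the default simulation condition."""
    return make_structured_population(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
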