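import numpy as np
import pytest

from phameth import simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.CommunityConfig(
        n_phages=10,
        n_bacteria=10,
        phage_length_range=(5_000, 8_000),
        n_samples=20,
        n_species=8,
        n_genera=4,
        n_families=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_community(small_config):
    return simulate.generate_community(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
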