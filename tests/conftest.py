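import numpy as np
import pytest

from tadloops import synthetic_data as sd


@pytest.fixture(scope="session")
def default_dataset():
    """One shared default synthetic dataset (seed 7)."""
    return sd.generate_dataset(sd.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def recovery_dataset():
    """Collision-free dataset with 200 loops at planted fraction 0.1."""
    return sd.generate_dataset(sd.SyntheticConfig(seed=7, n_loops=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
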