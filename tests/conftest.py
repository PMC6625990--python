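import numpy as np
import pytest

from flextail.synthetic import (build_core, default_system,
                                simulate_crosslinks)


@pytest.fixture(scope="session")
def small_core():
    """Compact 2-repeat solenoid core (64 residues)."""
    return build_core(2)


@pytest.fixture(scope="session")
def system0():
    """The packaged synthetic study system at seed 0."""
    return default_system(seed=0)


@pytest.fixture(scope="session")
def crosslinks0(system0):
    """Four true + three decoy crosslinks drawn on the seed-0 system."""
    return simulate_crosslinks(system0, n_true=4, n_decoy=3, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
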