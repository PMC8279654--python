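import numpy as np
import pytest

from surfprop import LangevinParams, TruePotentialParams, sample_window


@pytest.fixture(scope="session")
def default_potential():
    return TruePotentialParams()


@pytest.fixture(scope="session")
def default_dynamics():
    return LangevinParams()


@pytest.fixture(scope="session")
def flat_potential():
    """No well, wall far beyond the domain: a free particle."""
    return TruePotentialParams(well_depth=0.0, wall_position=100.0)


@pytest.fixture(scope="session")
def small_ladder(default_potential, default_dynamics):
    """21 umbrella windows at reduced length (2e4 stored frames each)."""
    centers = np.round(np.arange(1.0, 3.0001, 0.1), 10)
    return [
        sample_window(
            default_potential, default_dynamics, float(c), 1000.0, 2_000_000, seed=100 + i
        )
        for i, c in enumerate(centers)
    ]
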