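import numpy as np
import pytest

from depgame import (
    GameParams,
    PopulationParams,
    first_set_game,
    first_set_population,
)


@pytest.fixture(scope="session")
def gp() -> GameParams:
    return first_set_game()


@pytest.fixture(scope="session")
def pp() -> PopulationParams:
    return first_set_population()


@pytest.fixture(scope="session")
def small_pp() -> PopulationParams:
    """First-set composition on a 30x30 torus for cheaper ensemble tests."""
    return PopulationParams(n=30, male_fraction=0.493, rho_NE=0.188, rho_NE_S=0.05, rho_E_S=0.75)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
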