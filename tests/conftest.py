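import numpy as np
import pytest

from sympatry.synth import (
    LandscapeConfig,
    gen_climate,
    gen_demography,
    gen_landscape,
    gen_space_use,
)
from sympatry.truth import GenerativeTruth

YEARS = range(2006, 2016)


@pytest.fixture(scope="session")
def truth():
    return GenerativeTruth()


@pytest.fixture(scope="session")
def demography(truth):
    return gen_demography(8, YEARS, truth, seed=42)


@pytest.fixture(scope="session")
def climate(truth):
    return gen_climate(YEARS, truth, seed=42)


@pytest.fixture(scope="session")
def landscape():
    return gen_landscape(LandscapeConfig(nx=90, ny=90, years=list(YEARS)), seed=42)


@pytest.fixture(scope="session")
def space_use(demography, landscape, climate, truth):
    return gen_space_use(demography, landscape, climate, truth, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
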