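import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")

from foodspan import (
    DEFAULT_ENERGY_DENSITIES,
    default_schedule,
    make_curveset,
    preset_diet,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule("female")


@pytest.fixture(scope="session")
def schedule_male():
    return default_schedule("male")


@pytest.fixture(scope="session")
def curves():
    return make_curveset()


@pytest.fixture(scope="session")
def densities():
    return DEFAULT_ENERGY_DENSITIES


@pytest.fixture(scope="session")
def tw():
    return preset_diet("TW")


@pytest.fixture(scope="session")
def fa():
    return preset_diet("FA")


@pytest.fixture(scope="session")
def od():
    return preset_diet("OD")
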