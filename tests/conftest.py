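import pytest

from bnpce.hazard_schedules import SUBGROUPS
from bnpce.parameters import load_default_registry, point_estimate_set
from bnpce.synthetic_data import generate_life_table


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def point_params(registry):
    return point_estimate_set(registry)


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table()


@pytest.fixture(scope="session")
def subgroups():
    return SUBGROUPS
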