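"""Shared fixtures: one fitted survival stage per session plus economic
parameter sets, so individual tests stay fast."""

import pytest

from psmcea.pipeline import RunConfig, make_model_fn, run_survival_stage
from psmcea.psm import PSMConfig
from psmcea.synthetic import default_scenario, make_parameter_set


@pytest.fixture(scope="session")
def itt_scenario():
    return default_scenario("ITT")


@pytest.fixture(scope="session")
def itt_stage(itt_scenario):
    """Full survival stage (simulate -> KM -> reconstruct -> fit -> BMA)
    for the default trial-sized scenario; reused across test modules."""
    return run_survival_stage(itt_scenario, seed=7)


@pytest.fixture(scope="session")
def us_econ():
    return make_parameter_set("US")


@pytest.fixture(scope="session")
def china_econ():
    return make_parameter_set("China")


@pytest.fixture(scope="session")
def psm_config():
    return PSMConfig()


@pytest.fixture(scope="session")
def us_model_fn(itt_stage, us_econ, psm_config):
    """Economic model closure over the fitted ITT survivor grids."""
    return make_model_fn(itt_stage.grids, us_econ, psm_config)


@pytest.fixture(scope="session")
def us_base_ce(us_model_fn):
    return us_model_fn({})
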