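import numpy as np
import pytest

import maizeassim as ma


@pytest.fixture(scope="session")
def coeffs_pc0003():
    return ma.get_genetic_coefficients("PC0003")


@pytest.fixture(scope="session")
def basic_inputs():
    """Weather/soil/management for one mid-season planting."""
    weather = ma.gen_weather(1)
    soil = ma.gen_soil(101)
    mgmt = ma.Management(planting_doy=125)
    return weather, soil, mgmt


@pytest.fixture(scope="session")
def plain_bundle():
    """A no-drought known-truth scenario."""
    spec = ma.ScenarioSpec(planting_doy=125, maturity_group="PC0003")
    return ma.gen_scenario(21, spec)


@pytest.fixture(scope="session")
def drought_bundle():
    """A rain-fed truth season with a strong mid-season drought."""
    spec = ma.ScenarioSpec(
        planting_doy=125, maturity_group="PC0003",
        drought=ma.DroughtSpec(start_doy=185, end_doy=225, factor=0.1),
    )
    return ma.gen_scenario(11, spec)


@pytest.fixture(scope="session")
def truth_lai_lookup(drought_bundle):
    """Daily LAI of the drought truth trajectory as a DOY mapping."""
    trace = drought_bundle.truth_result.trace
    return dict(zip(trace["doy"].astype(int), trace["lai"]))
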