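import pytest
from hypothesis import HealthCheck, settings

import normdose as nd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def coefficients() -> nd.DoseCoefficients:
    return nd.load_dose_coefficients()


@pytest.fixture(scope="session")
def materials() -> dict[str, nd.NuclideVector]:
    return nd.load_materials()


@pytest.fixture(scope="session")
def nodules(materials) -> nd.NuclideVector:
    return materials["nodules_bulk"]


@pytest.fixture(scope="session")
def slag(materials) -> nd.NuclideVector:
    return materials["slag_3rd_reduction"]


@pytest.fixture(scope="session")
def filter_dust(materials) -> nd.NuclideVector:
    return materials["filter_dust_1st_reduction"]


@pytest.fixture(scope="session")
def transport_scenario() -> nd.Scenario:
    return nd.load_scenario("transport")


@pytest.fixture(scope="session")
def processing_scenario() -> nd.Scenario:
    return nd.load_scenario("processing_plant")
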