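import numpy as np
import pytest
from dataclasses import replace

from fairmbf import PhantomSpec, get_protocol, make_geometry, simulate_series


@pytest.fixture(scope="session")
def diastole_protocol():
    return get_protocol("FAIR-PI2_D")


@pytest.fixture(scope="session")
def systole_pi2():
    return get_protocol("FAIR-PI2_S")


@pytest.fixture(scope="session")
def systole_cs3():
    return get_protocol("FAIR-CS3_S")


@pytest.fixture
def clean_spec():
    """Default phantom with every corruption source switched off."""
    return PhantomSpec().noiseless()


@pytest.fixture
def asym_spec():
    """Noiseless phantom with the RV blood pool (rotationally asymmetric)."""
    return replace(PhantomSpec(rv_radius_mm=12.0).noiseless())


@pytest.fixture(scope="session")
def crop_slices():
    # default 64 px ROI in the 150 px grid
    return (slice(43, 107), slice(43, 107))


@pytest.fixture
def clean_series(clean_spec, diastole_protocol):
    return simulate_series(clean_spec, diastole_protocol)
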