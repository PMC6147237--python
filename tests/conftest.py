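import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from receptox import data, h1
from receptox.calibration import CalibrationConfig, calibrate
from receptox.network import find_steady_state


@pytest.fixture(scope="session")
def table1():
    return data.table1_assay()


@pytest.fixture(scope="session")
def calibrated(table1):
    """One calibration of the H1 model against the measured assay table,
    shared by every test that needs the fitted model."""
    return calibrate(table1, CalibrationConfig(seed=1))


@pytest.fixture(scope="session")
def calibrated_steady(calibrated):
    """(network, stimulated steady state, spec) for the calibrated model."""
    spec = calibrated.spec
    net = h1.build_h1_network(spec)
    ss = find_steady_state(net, h1.default_state(spec, stimulated=True, network=net))
    return net, ss, spec
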