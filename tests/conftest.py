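import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from lfaquant.calibration import fit_calibration
from lfaquant.fixtures import load_fixture_readings
from lfaquant.synthetic import SyntheticStripSpec, generate_strip


@pytest.fixture(scope="session")
def fixture_readings():
    return load_fixture_readings()


@pytest.fixture(scope="session")
def fixture_model(fixture_readings):
    model, _ = fit_calibration(fixture_readings)
    return model


@pytest.fixture(scope="session")
def training_readings(fixture_readings):
    return [r for r in fixture_readings if r.set_id in (1, 2)]


@pytest.fixture(scope="session")
def test_set_readings(fixture_readings):
    return [r for r in fixture_readings if r.set_id == 3]


@pytest.fixture()
def noiseless_strip():
    spec = SyntheticStripSpec(test_strength=0.5, noise_sd=0.0)
    return generate_strip(spec)
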