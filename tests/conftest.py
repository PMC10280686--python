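import numpy as np
import pytest
from hypothesis import settings

from walkspeed import CameraModel, FlightState, ground_footprint

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    """Sensor defaults: 84 degree FOV, 1920x1080 at 30 fps."""
    return CameraModel()


@pytest.fixture(scope="session")
def flight40() -> FlightState:
    return FlightState(altitude_m=40.0)


@pytest.fixture(scope="session")
def footprint40(camera, flight40):
    return ground_footprint(camera, flight40)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
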