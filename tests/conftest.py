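import datetime as dt
import random

import pytest

from phenoflow import config as cfgmod
from phenoflow import privacy, simulator


@pytest.fixture(scope="session")
def keypair():
    """One study keypair for the whole session (keygen is the slow part)."""
    return privacy.generate_keypair(2048, rng=random.Random(20240101))


@pytest.fixture(scope="session")
def master_key():
    return bytes(range(32))


@pytest.fixture(scope="session")
def default_cfg():
    return cfgmod.default_config("test-study")


@pytest.fixture(scope="session")
def light_cfg():
    """Default study thinned to low-volume sampling for fast simulations."""
    base = cfgmod.default_config("test-study-light")
    settings = []
    for s in base.sensor_settings:
        if s.stream_name == cfgmod.StreamName.accelerometer:
            s = s.model_copy(update={"on_duration": 60.0, "off_duration": 540.0, "nominal_rate": 5.0})
        settings.append(s)
    return base.model_copy(update={"sensor_settings": settings, "audio_max_duration": 20.0})


@pytest.fixture(scope="session")
def profile():
    return simulator.default_profile(rng_seed=11)


START = dt.date(2024, 1, 1)
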