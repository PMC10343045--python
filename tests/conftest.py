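import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import multisync as ms

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bench_session():
    """Bench-style recording: presses on the electrodes, no respiration."""
    cfg = ms.SessionConfig(
        duration=40.0,
        press_times=(8.0, 16.0, 24.0, 32.0),
        ip_breath_amplitude=0.0,
        inter_device_offset=0.15,
    )
    return ms.simulate_session(cfg, rng_seed=11)


@pytest.fixture(scope="session")
def clinical_session():
    """Infant-style session: stimuli, breathing, cardiac coupling, offset."""
    cfg = ms.SessionConfig(
        duration=60.0,
        stimulus_times=(15.0, 27.0, 39.0),
        press_times=(50.0,),
        inter_device_offset=0.2,
    )
    return ms.simulate_session(cfg, rng_seed=7)
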