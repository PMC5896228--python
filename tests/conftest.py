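import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirsrls import BlockDesign, EvokedResponse, InterferenceModel, generate_recording

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def design():
    """The study paradigm: 20 s stim / 20 s rest, 10 blocks, 200 s baseline."""
    return BlockDesign()


@pytest.fixture
def quiet_recording(design):
    """Interference- and noise-free recording: long channel is pure evoked/pvef."""
    interference = InterferenceModel(cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0, noise_sd=0.0)
    return generate_recording(design, interference, EvokedResponse(), seed=0)


@pytest.fixture
def default_recording(design):
    return generate_recording(design, InterferenceModel(), EvokedResponse(), seed=42)
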