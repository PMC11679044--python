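import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stripspec import SimulatorConfig, Spectrum, default_truth_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def truth_model():
    return default_truth_model()


@pytest.fixture
def noiseless_config():
    return SimulatorConfig(noise_fraction=0.0)


@pytest.fixture
def default_config():
    return SimulatorConfig()


@pytest.fixture
def flat_spectrum():
    wl = np.arange(300.0, 700.0, 5.0)
    return Spectrum(wl, np.full(wl.shape, 5.0), "C")


def write_two_column(path, rows, delimiter=" "):
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write(delimiter.join(str(v) for v in row) + "\n")
    return path
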