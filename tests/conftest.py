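import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mp2flaws.presets import TISSUES, table1_protocol

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tissues():
    return dict(TISSUES)


@pytest.fixture(scope="session")
def wm(tissues):
    return tissues["WM"]


@pytest.fixture(scope="session")
def gm(tissues):
    return tissues["GM"]


@pytest.fixture(scope="session")
def csf(tissues):
    return tissues["CSF"]


@pytest.fixture(scope="session")
def seq4000():
    """Initial TR=4000 ms protocol (TI 650/2220, TR_GRE 7.26, 180 exc)."""
    return table1_protocol(4000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
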