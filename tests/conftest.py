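import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from palinsert.detect import call_panel
from palinsert.panel import build_consensus_element, build_panel, default_panel_config

PANEL_SEED = 1


@pytest.fixture(scope="session")
def panel():
    return build_panel(default_panel_config(seed=PANEL_SEED))


@pytest.fixture(scope="session")
def element():
    return build_consensus_element(PANEL_SEED)


@pytest.fixture(scope="session")
def panel_calls(panel):
    return call_panel(panel)


@pytest.fixture(scope="session")
def noisy_panel():
    return build_panel(default_panel_config(seed=PANEL_SEED, mutation_rate=0.02))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)
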