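import numpy as np
import pytest

from conjoint.scenarios import run_scenario


@pytest.fixture(scope="session")
def fig1_right():
    """Coupled untreated baseline, computed once per session."""
    return run_scenario("fig1_right")


@pytest.fixture(scope="session")
def fig1_left():
    """Decoupled untreated baseline."""
    return run_scenario("fig1_left")


@pytest.fixture
def rng():
    return np.random.default_rng(20100615)
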