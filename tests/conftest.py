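import numpy as np
import pytest

from posturokit import (
    AnalysisConfig,
    SwaySimParams,
    preprocess_recording,
    simulate_reference_cohort,
    simulate_sway_recording,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def quiet_recording():
    """Clean 30 s quiet-stance recording, gravity on Z."""
    return simulate_sway_recording(SwaySimParams(seed=11))


@pytest.fixture(scope="session")
def sway_signal(quiet_recording, config):
    return preprocess_recording(quiet_recording, config)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic reference cohort (277 subjects, 100 fallers)."""
    return simulate_reference_cohort(seed=22)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
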