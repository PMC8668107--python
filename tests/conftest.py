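import numpy as np
import pytest

from nsinet.params import ModelParams, default_params
from nsinet.stimuli import make_step
from nsinet.sensillum import run_sensilla


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return default_params()


@pytest.fixture(scope="session")
def step_waveform():
    """500 ms step at mid concentration with 500 ms settle time."""
    return make_step(2e-3, 0.0, 500.0, 500.0, 1300.0, 0.1)


@pytest.fixture(scope="session")
def step_run(params, step_waveform):
    """One control-variant sensillum run, shared across read-only tests."""
    return run_sensilla(step_waveform, params, "control", seed=0)
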