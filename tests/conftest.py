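import numpy as np
import pytest

from ftcd.config import load_config
from ftcd.simulate import SimulationSpec, simulate_recording


@pytest.fixture(scope="session")
def default_cfg():
    return load_config({})


@pytest.fixture(scope="session")
def sim_session():
    """One clean simulated word-generation session (23 trials, left-dominant)."""
    spec = SimulationSpec(seed=11)
    rec, truth = simulate_recording(spec)
    return spec, rec, truth


@pytest.fixture(scope="session")
def processed_session(sim_session):
    """The clean session run through the full default pipeline."""
    from ftcd.pipeline import process_recording

    spec, rec, truth = sim_session
    cfg = load_config({})
    return process_recording(rec, cfg)
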