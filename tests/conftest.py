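import pytest
from hypothesis import settings

import scn_coupling as sc

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    """Short default-condition recording config shared across tests."""
    return sc.SimulationConfig(duration_h=96.0, seed=42)


@pytest.fixture(scope="session")
def recording(default_config):
    return sc.simulate_recording(default_config)


@pytest.fixture(scope="session")
def analysis(recording):
    return sc.analyze_recording_obj(recording, compute_recovery=True)


@pytest.fixture(scope="session")
def uncoupled_recording():
    cfg = sc.SimulationConfig(duration_h=96.0, seed=43)
    return sc.simulate_recording(cfg, coupled=False)
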