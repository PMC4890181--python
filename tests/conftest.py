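import numpy as np
import pytest
from hypothesis import settings

from thylakoid_biophys import kcl_gradient, symmetric_kcl
from thylakoid_biophys import synthetic_data as synth

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kcl_100():
    return symmetric_kcl(100.0)


@pytest.fixture(scope="session")
def kcl_300_100():
    return kcl_gradient(300.0, 100.0)


@pytest.fixture(scope="session")
def default_gating():
    return synth.ChannelGatingParams()


@pytest.fixture(scope="session")
def positive_branch_traces(default_gating):
    """60-s KCl recordings at +40/+60/+80 mV, noise 0.8 pA (shared: slow)."""
    config = synth.RecordingConfig(
        holding_potentials_mv=(40.0, 60.0, 80.0),
        duration_s=60.0,
        sampling_rate_hz=5000.0,
        noise_sd_pa=0.8,
        seed=20260930,
    )
    return synth.simulate_channel_trace(default_gating, config)


@pytest.fixture(scope="session")
def noiseless_ecs_trace():
    return synth.simulate_ecs_trace(
        synth.EcsSimParams(s_light=1.0, f_dpsi=0.6, tau_decay_ms=25.0)
    )
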