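import pytest
from hypothesis import settings

from mitohfpn import Condition, build_model, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def control_model():
    return build_model(Condition.control())


@pytest.fixture(scope="session")
def c1193_model():
    return build_model(Condition.c1193())


@pytest.fixture(scope="session")
def control_sim(control_model):
    net, _ = control_model
    return simulate(net, t_end=15.0, dt=0.001, sample_every=0.5)


@pytest.fixture(scope="session")
def c1193_sim(c1193_model):
    net, _ = c1193_model
    return simulate(net, t_end=15.0, dt=0.001, sample_every=0.5)
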