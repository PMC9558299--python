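import pytest
from hypothesis import settings

from coralsym import Environment, ParameterSet, default_params, init_healthy

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def params():
    """Reference two-symbiont parameter set (sensitive, tolerant)."""
    return default_params()


@pytest.fixture(scope="session")
def single_sensitive(params):
    return ParameterSet(host=params.host, symbionts=(params.symbionts[0],))


@pytest.fixture(scope="session")
def benign_env():
    """Mild conditions well inside the healthy basin."""
    return Environment(light=20.0, din=1e-7, prey=1e-7)


@pytest.fixture(scope="session")
def healthy_pair(params, benign_env):
    return init_healthy(params, benign_env)
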