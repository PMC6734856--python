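import numpy as np
import pytest

from cathsim import SessionConfig, build_scenario, generate_environment


@pytest.fixture(scope="session")
def env():
    return generate_environment(0)


@pytest.fixture(scope="session")
def scenario1(env):
    return build_scenario(1, env)


@pytest.fixture(scope="session")
def free_scenario(env):
    return build_scenario("free", env)


@pytest.fixture()
def config():
    # dt=0.1 keeps simulated sessions short; all invariants are dt-free
    return SessionConfig(dt=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
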