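import pytest
from hypothesis import settings

from epicua import default_config, generate_inputs, run_condition

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lgs_config():
    return default_config("LGS")


@pytest.fixture(scope="session")
def ds_config():
    return default_config("DS")


@pytest.fixture(scope="session")
def lgs_bundle(lgs_config):
    return generate_inputs(lgs_config, seed=1)


@pytest.fixture(scope="session")
def lgs_result(lgs_config):
    return run_condition(lgs_config, seed=1)


@pytest.fixture(scope="session")
def ds_result(ds_config):
    return run_condition(ds_config, seed=1)
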