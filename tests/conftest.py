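import pytest

from dsmcell.config import build_model
from dsmcell.defaults import default_config
from dsmcell.simulator import initial_state


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def model(cfg):
    return build_model(cfg)


@pytest.fixture(scope="session")
def equilibrated(model):
    return initial_state(model)
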