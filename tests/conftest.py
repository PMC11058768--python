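import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from tundracap import DowngradeConfig, HerbivoreParams, SyntheticConfig, generate_stack


@pytest.fixture(scope="session")
def default_stack():
    """A 40x40 four-band synthetic landscape with the default structure."""
    return generate_stack(SyntheticConfig(n_rows=40, n_cols=40, seed=7))


@pytest.fixture()
def config():
    return DowngradeConfig()


@pytest.fixture()
def params():
    return HerbivoreParams()
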