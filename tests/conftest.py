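import pytest
from hypothesis import HealthCheck, settings

from npmdj import load_fixtures, load_model_config

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return load_model_config()


@pytest.fixture(scope="session")
def t3_rows():
    return load_fixtures("T3")


@pytest.fixture(scope="session")
def t4_rows():
    return load_fixtures("T4")
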