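import pytest
from hypothesis import HealthCheck, settings

from aedesrr import ParamSet, wildtype_equilibrium

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> ParamSet:
    return ParamSet()


@pytest.fixture(scope="session")
def default_eq(default_params):
    return wildtype_equilibrium(default_params)
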