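import pytest
from hypothesis import HealthCheck, settings

from markovcea import packaged_base_case

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_inputs():
    """The packaged base-case configuration (published inputs)."""
    return packaged_base_case()


@pytest.fixture(scope="session")
def base_arms(base_inputs):
    return {a.name: a for a in base_inputs.arms}
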