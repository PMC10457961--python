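import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230818)


@pytest.fixture(scope="session")
def default_bioassay():
    """One 200-tick simulated adult immersion test under the default design."""
    from ticksay.synthetic_data import SyntheticBioassayConfig, generate_bioassay

    return generate_bioassay(SyntheticBioassayConfig(seed=42))
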