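import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epishore import make_fixture_reference

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def spec():
    """Synthetic amplicon with the canonical 2/9/13 O/S/I CpG layout."""
    return make_fixture_reference(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
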