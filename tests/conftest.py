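import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (fast) with all three groups present."""
    from micrographia.simulate import generate_cohort, load_default_config

    cfg = load_default_config()
    cfg.group_sizes = {"PD": 60, "ET": 25, "HC": 20}
    return generate_cohort(cfg, seed=2024)


@pytest.fixture(scope="session")
def default_cohort():
    """The packaged default configuration at published group sizes."""
    from micrographia.simulate import generate_cohort

    return generate_cohort(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
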