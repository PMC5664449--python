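import pytest
from hypothesis import HealthCheck, settings

from occutail.simulate import SimConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """A 300-gene simulation shared by closed-loop unit tests."""
    return generate(
        SimConfig(n_genes=300, seed=7, target_fraction=0.1, n_random_sets=20)
    )


@pytest.fixture(scope="session")
def study_sim():
    """A full-scale simulation at the default study conditions."""
    return generate(SimConfig(seed=1))
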