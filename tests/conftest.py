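import pytest
from hypothesis import HealthCheck, settings

from hopforecast import GeneratorConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_table():
    """Full-size squad table at the default generator settings."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def high_signal_table():
    """Default design with low outcome noise: the forecastable regime."""
    return generate_dataset(GeneratorConfig(seed=1, noise_sd=0.5))


@pytest.fixture(scope="session")
def small_table():
    """A small table (2 athletes x 5 days x 2 sessions) for fast pipeline tests."""
    return generate_dataset(GeneratorConfig(n_athletes=2, n_days=5, sessions_per_day=2, seed=7))
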