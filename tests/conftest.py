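import pytest
from hypothesis import HealthCheck, settings

from lobesia.features import aggregate_daily
from lobesia.simulate import SimWeatherParams, simulate_weather_year

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calm_records():
    """One noise-free, gap-free station-year (2009) of semi-hourly records."""
    params = SimWeatherParams(noise_sd=0.0, gap_prob_per_day=0.0, rain_prob_per_day=0.2)
    return simulate_weather_year(params, seed=11)


@pytest.fixture(scope="session")
def calm_daily(calm_records):
    return aggregate_daily(calm_records)
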