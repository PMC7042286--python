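import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from maizestress import GeneratorConfig, generate_dataset
from maizestress.stress_features import WEATHER_COLUMNS

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_weather(start, tmax, tmin=None, precip=None, vapour_pressure=None):
    """Build a daily weather table from per-day arrays, filling the unused
    columns (day length, radiation, snow) with benign constants."""
    tmax = np.asarray(tmax, float)
    n = len(tmax)
    if tmin is None:
        tmin = tmax - 10.0
    if precip is None:
        precip = np.zeros(n)
    if vapour_pressure is None:
        vapour_pressure = np.full(n, 1500.0)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n),
            "day_length_s": 45000.0,
            "solar_radiation_wm2": 250.0,
            "tmax_c": tmax,
            "tmin_c": np.asarray(tmin, float),
            "precip_mm": np.asarray(precip, float),
            "vapour_pressure_pa": np.asarray(vapour_pressure, float),
            "swe_kgm2": 0.0,
        }
    )[WEATHER_COLUMNS]


@pytest.fixture(scope="session")
def small_dataset():
    """A reusable synthetic trial network, big enough for every stage."""
    config = GeneratorConfig(n_environments=40, n_hybrids=20, seed=11)
    return generate_dataset(config)
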