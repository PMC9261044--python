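import numpy as np
import pandas as pd
import pytest

from actigeo import synthetic_city as sc


@pytest.fixture(scope="session")
def small_city():
    """16-DA grid city with default amenity layers."""
    return sc.generate_city(16, das_per_tract=4, seed=3)


@pytest.fixture(scope="session")
def small_cohort_inputs(small_city):
    """(city, roster, exposure_da, tract_measures, weather) for quick runs."""
    city = small_city
    roster = sc.generate_cohort(6, city, seed=3)
    exposure_da, tract_measures = sc.generate_exposure_table(city, seed=3)
    weather = sc.generate_weather(pd.date_range("2018-06-04", periods=3), seed=3)
    return city, roster, exposure_da, tract_measures, weather


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
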