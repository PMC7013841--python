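import numpy as np
import pandas as pd
import pytest

from aqra.breakpoints import load_breakpoint_table
from aqra.simulate import (
    GOVERNORATES,
    PollutantGenParams,
    RegistryGenParams,
    simulate_daily_exposure,
    simulate_registry,
)


@pytest.fixture(scope="session")
def kuwait_table():
    return load_breakpoint_table()


@pytest.fixture(scope="session")
def complete_exposure():
    """Two years of complete (no-outage) daily exposure for all governorates."""
    params = PollutantGenParams(seed=1234, missing_rates={})
    return simulate_daily_exposure(params, 730)


@pytest.fixture(scope="session")
def small_registry(complete_exposure):
    """A few hundred visits with the default planted DAS-28 effects."""
    params = RegistryGenParams(n_patients=120, seed=99)
    return simulate_registry(params, complete_exposure)


def hourly_frame(values_by_hour, pollutant="PM10", governorate="Ahmadi",
                 station="KEPA-AHMA", date="2015-06-01"):
    """Build an hourly table for one station/pollutant from {hour: value}."""
    start = pd.Timestamp(date)
    rows = [
        {
            "station_id": station,
            "governorate": governorate,
            "timestamp": start + pd.Timedelta(hours=h),
            "pollutant": pollutant,
            "concentration": v,
        }
        for h, v in values_by_hour.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def make_hourly():
    return hourly_frame
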