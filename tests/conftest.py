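from datetime import date

import numpy as np
import pandas as pd
import pytest

from aeromig import StationConfig, SeasonWindows
from aeromig import synthetic as syn


@pytest.fixture
def station() -> StationConfig:
    """A lowland tropical radar site (Magdalena-valley-like)."""
    return StationConfig("TEST", 6.93, -73.76, 80.0, -5.0)


@pytest.fixture
def short_fall() -> SeasonWindows:
    """A two-week fall window: keeps generator-backed tests fast."""
    return SeasonWindows(fall_start=(9, 1), fall_end=(9, 14))


@pytest.fixture
def tiny_series(station):
    """A hand-built two-profile series with one missing velocity."""
    from aeromig import ProfileTimeSeries

    df = pd.DataFrame(
        {
            "datetime": pd.to_datetime(
                ["2021-09-05T02:00:00Z"] * 3 + ["2021-09-05T03:00:00Z"] * 3
            ),
            "height": [0.0, 100.0, 200.0] * 2,
            "eta": [11.0, 22.0, 0.0, 5.5, 11.0, 2.2],
            "u": [1.0, 2.0, np.nan, 0.5, 1.5, 1.0],
            "v": [3.0, 4.0, np.nan, 2.5, 3.5, 2.0],
        }
    )
    return ProfileTimeSeries(station=station, data=df)


@pytest.fixture(scope="session")
def noisefree_scenario():
    """A generated noise-free scenario shared across tests (exact recovery)."""
    win = SeasonWindows(fall_start=(9, 1), fall_end=(9, 10))
    params = syn.preset("noisefree", seed=11, windows=win, scan_interval_min=60)
    grid = syn.gen_atmosphere(params)
    nights = syn.gen_truth_nights(params)
    series, manifest = syn.gen_profiles(nights, grid, params)
    return params, grid, nights, series, manifest
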