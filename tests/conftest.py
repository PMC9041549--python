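import datetime as dt

import numpy as np
import pytest

from roostnrg import (
    BioenergeticParams,
    RoostTemperatureGrid,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def params():
    return BioenergeticParams()


@pytest.fixture(scope="session")
def small_config():
    """Two-week mid-summer study: small but warm enough to overheat."""
    return SimulationConfig(
        seed=42,
        start_date=dt.date(2019, 6, 15),
        end_date=dt.date(2019, 6, 28),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def make_grid(temps, box_id="B1", date=dt.date(2019, 6, 1)):
    """Grid helper: broadcast a scalar/per-hour vector to the 24 x 12 matrix."""
    arr = np.asarray(temps, dtype=float)
    if arr.ndim == 0:
        arr = np.full((24, 12), float(arr))
    elif arr.ndim == 1:
        arr = np.repeat(arr[:, None], 12, axis=1)
    return RoostTemperatureGrid(box_id=box_id, date=date, temps=arr)


@pytest.fixture
def grid_factory():
    return make_grid
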