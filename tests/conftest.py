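import numpy as np
import pandas as pd
import pytest

from heatmort.config import StudyConfig
from heatmort.pipeline import run_scenario
from heatmort.synthetic import scenario_preset, simulate_all


@pytest.fixture(scope="session")
def small_scenario():
    """4 districts, 4 years: cheap but exercises every group quadrant."""
    return scenario_preset("acute_only", rng_seed=7, n_districts=4, n_cells=8, years=4)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    return simulate_all(small_scenario)


@pytest.fixture(scope="session")
def small_config(small_scenario):
    return small_scenario.study_config(mc_replicates=500, rng_seed=7)


@pytest.fixture(scope="session")
def small_results(small_scenario, small_config):
    """Full district pipeline on the small scenario, shared across tests."""
    data, district, _ = run_scenario(small_scenario, small_config)
    return data, district


def make_daily_frame(district_id, start, periods, temps=None, rates=None):
    dates = pd.date_range(start, periods=periods, freq="D")
    frame = pd.DataFrame({"district_id": district_id, "date": dates})
    if temps is not None:
        frame["mean_temp"] = np.asarray(temps, dtype=float)
    if rates is not None:
        frame["rate"] = np.asarray(rates, dtype=float)
    return frame
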