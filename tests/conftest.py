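import warnings

import numpy as np
import pandas as pd
import pytest

from hemsits.config import AnalysisConfig, SimulationConfig
from hemsits.missions import assign_period
from hemsits.simulate import generate_missions

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A light registry (~600 missions) for fast pipeline-level tests."""
    return SimulationConfig(missions_per_month=6.0, seed=777)


@pytest.fixture(scope="session")
def small_registry(small_config):
    missions, patients = generate_missions(small_config)
    for col in ("alarm_time", "takeoff_time", "on_scene_time"):
        missions[col] = pd.to_datetime(missions[col], utc=True)
    missions = assign_period(missions, small_config.intervention_date)
    return missions, patients


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: every test sees the same fresh, deterministic stream
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()
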