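import pandas as pd
import pytest
from hypothesis import settings

from ensorice import fixtures
from ensorice.crop_surrogate import SurrogateParams

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")

DEFAULT_BOUNDS = {
    "potential_yield": (3.0, 12.0),
    "heat_sensitivity": (0.0, 2.0),
    "water_sensitivity": (0.0, 1.0),
    "t_opt": (24.0, 32.0),
    "water_requirement": (100.0, 800.0),
}


@pytest.fixture(scope="session")
def plot_table() -> pd.DataFrame:
    """Packaged plot-level observed/simulated yields (calibration experiments)."""
    return fixtures.load_plot_yields()


@pytest.fixture(scope="session")
def risk_table() -> pd.DataFrame:
    return fixtures.load_risk_areas()


@pytest.fixture(scope="session")
def yield_changes() -> pd.DataFrame:
    return fixtures.load_yield_changes()


@pytest.fixture(scope="session")
def production_tables():
    return fixtures.load_production()


@pytest.fixture
def default_params() -> SurrogateParams:
    return SurrogateParams()


@pytest.fixture
def bounds() -> dict:
    return dict(DEFAULT_BOUNDS)


def reference_weather(params: SurrogateParams, days: int | None = None) -> pd.DataFrame:
    """Stress-free season weather: temperature at optimum, water at requirement.

    Rainfall is spread so the first ``season_length`` days (the window the
    surrogate reads) deliver exactly the seasonal water requirement.
    """
    days = days if days is not None else params.season_length + 5
    return pd.DataFrame(
        {
            "date": pd.date_range("2012-04-01", periods=days),
            "tmean": params.t_opt,
            "rainfall": params.water_requirement / params.season_length,
        }
    )
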