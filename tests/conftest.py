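import numpy as np
import pandas as pd
import pytest

from sorgenv import crop_sim, synthetic_data


@pytest.fixture(scope="session")
def cultivar():
    return crop_sim.CULTIVAR_PRESETS["hybrid_1"]


@pytest.fixture(scope="session")
def soil():
    return crop_sim.default_soil_profile()


@pytest.fixture(scope="session")
def dry_weather():
    """Ten years of dry-west synthetic weather."""
    return synthetic_data.gen_weather(
        synthetic_data.SITE_PRESETS["dry_west"], 2000, 10, seed=11
    )


@pytest.fixture(scope="session")
def wet_weather():
    """Ten years of wet-east synthetic weather."""
    return synthetic_data.gen_weather(
        synthetic_data.SITE_PRESETS["wet_east"], 2000, 10, seed=11
    )


def make_irrigated_weather(n_days: int = 220, tmax: float = 29.0, tmin: float = 17.0):
    """Mild, rain-saturated weather: no water or heat stress possible."""
    dates = pd.date_range("2001-04-01", periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "tmax": np.full(n_days, tmax),
            "tmin": np.full(n_days, tmin),
            "rain": np.full(n_days, 30.0),
            "radn": np.full(n_days, 20.0),
        }
    )


@pytest.fixture()
def irrigated_weather():
    return make_irrigated_weather()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario grid used by the pipeline tests."""
    from sorgenv import pipeline

    config = pipeline.load_config()
    config["weather"] = {"sites": ["dry_west", "wet_east"], "start_year": 2000, "n_years": 8}
    config["scenarios"]["sowing_dates"] = ["05-15", "06-01"]
    config["scenarios"]["managements"] = [{"density": 28.0, "n_label": 138.0}]
    config["cultivars"] = ["hybrid_1"]
    return config
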