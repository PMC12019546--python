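import numpy as np
import pandas as pd
import pytest

from grazecast import climate as cl
from grazecast import farm as fm
from grazecast import soil as so


@pytest.fixture
def monthly_records():
    """Two constant synthetic years of monthly weather."""
    rows = []
    for y in (2000, 2001):
        for m in range(1, 13):
            rows.append((y, m, 60.0, 12.0, 80.0))
    return pd.DataFrame(
        rows, columns=["year", "month", "rain", "tmean", "pan_evap"]
    )


@pytest.fixture
def climate_series(monthly_records):
    return cl.ClimateSeries(site_id="fixture", records=monthly_records)


@pytest.fixture
def daily_csv(tmp_path):
    """A 12-month daily weather CSV with exact per-month column sums."""
    rng = np.random.default_rng(42)
    dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
    df = pd.DataFrame({
        "date": dates.strftime("%Y-%m-%d"),
        "rain": rng.gamma(0.5, 4.0, len(dates)),
        "tmax": 18 + 6 * np.sin(2 * np.pi * dates.dayofyear / 365),
        "tmin": 8 + 5 * np.sin(2 * np.pi * dates.dayofyear / 365),
        "evap": rng.uniform(1, 6, len(dates)),
    })
    path = tmp_path / "weather.csv"
    df.to_csv(path, index=False)
    return path, df


@pytest.fixture
def beef_config():
    return fm.beef_farm()


@pytest.fixture
def tiny_farm():
    """A two-class toy herd for hand-checkable arithmetic."""
    return fm.FarmConfig(
        farm_id="toy",
        grazed_area_ha=100.0,
        animal_classes=(
            fm.AnimalClass("cows", 10, 500, 10.0, "meat", 200.0, 60.0,
                           "cattle"),
            fm.AnimalClass("ewes", 100, 55, 1.5, "wool", 5.0, 10.0,
                           "sheep"),
        ),
    )


@pytest.fixture
def topsoil_params():
    return so.SoilLayerParams(
        layer="0-30cm", clay_pct=30.0, depth_cm=30.0, k=so.TOPSOIL_K,
        initial_soc=60.0, iom=3.0,
    )


@pytest.fixture
def deep_params():
    return so.SoilLayerParams(
        layer="30-100cm", clay_pct=35.0, depth_cm=70.0, k=so.DEEP_K,
        initial_soc=40.0, iom=4.0,
    )
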