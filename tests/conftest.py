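import numpy as np
import pandas as pd
import pytest

from chillcurve.weather import ChamberRegime


@pytest.fixture
def standard_regime():
    """25 deg C x 14 h (light) / 15 deg C x 10 h (dark), base 5 deg C."""
    return ChamberRegime()


@pytest.fixture
def daily_weather():
    """Ten contiguous autumn days cooling from 14 to 5 deg C."""
    dates = pd.date_range("2021-10-20", periods=10, freq="D")
    tmean = np.linspace(14.0, 5.0, 10)
    return pd.DataFrame(
        {"date": dates, "tmean": tmean, "tmax": tmean + 4.0, "tmin": tmean - 4.0}
    )


def make_daily(tmeans, start="2021-11-01", half_range=4.0):
    """Daily weather frame with constant diurnal half-range."""
    tm = np.asarray(tmeans, float)
    return pd.DataFrame(
        {
            "date": pd.date_range(start, periods=tm.size, freq="D"),
            "tmean": tm,
            "tmax": tm + half_range,
            "tmin": tm - half_range,
        }
    )
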