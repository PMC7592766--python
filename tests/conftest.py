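from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tidetrack as tt

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_series(depths, start="2018-07-01", interval_s=600.0, temps=None,
                censored=None, tag_id="T1"):
    """Build a DepthTempSeries from a depth array at a fixed cadence."""
    depths = np.asarray(depths, dtype=float)
    ts = pd.date_range(start, periods=len(depths), freq=f"{int(interval_s)}s",
                       tz="UTC")
    df = pd.DataFrame({
        "timestamp": ts,
        "depth": depths,
        "temperature": (np.asarray(temps, dtype=float) if temps is not None
                        else np.full(len(depths), 12.0)),
        "censored": (np.asarray(censored, dtype=bool) if censored is not None
                     else np.zeros(len(depths), dtype=bool)),
    })
    return tt.DepthTempSeries(tag_id=tag_id, samples=df,
                              nominal_depth_interval=interval_s,
                              nominal_temp_interval=interval_s)


@pytest.fixture(scope="session")
def env():
    """The default 25x25 synthetic shelf sea."""
    return tt.make_environment(1)


@pytest.fixture(scope="session")
def all_sea_env():
    """A landless uniform grid for diffusion moment checks."""
    n = 41
    lon = np.linspace(-4.0, -2.0, n)
    lat = np.linspace(49.5, 51.5, n)
    ones = np.ones((n, n))
    return tt.EnvironmentGrid(
        lon_centers=lon, lat_centers=lat, bathymetry=50.0 * ones,
        tide_amplitude=1.0 * ones, tide_phase=0.0 * ones,
        temp_mean=14.0 * ones, temp_seasonal_amplitude=7.0 * ones)
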