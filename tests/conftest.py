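import numpy as np
import pandas as pd
import pytest

import duvb
from duvb import cw_duvb, series_io, synthetic_data as syn


@pytest.fixture(scope="session")
def dublin_sim() -> duvb.DailyDoseSeries:
    """Six simulated years at Dublin with 10% blackout days."""
    cfg = syn.ScenarioConfig(locations=(duvb.capital("Dublin"),),
                             years=(2004, 2009), blackout_rate=0.10, seed=42)
    return syn.generate_series(cfg)["Dublin"]


@pytest.fixture(scope="session")
def trio_cw_library() -> dict:
    """Monthly CW profiles for a south/mid/north latitude trio (5 sim years)."""
    cfg = syn.ScenarioConfig(
        locations=(duvb.capital("Athens"), duvb.capital("Dublin"),
                   duvb.capital("Reykjavik")),
        years=(2004, 2008), blackout_rate=0.03, seed=11)
    series = syn.generate_series(cfg)
    return {name: cw_duvb.monthly_cw(cw_duvb.cw_series(series_io.impute_blackouts(s)))
            for name, s in series.items()}


@pytest.fixture()
def sinusoid_series() -> duvb.DailyDoseSeries:
    """Noise-free annual sinusoid peaking at day-of-year 172, six years."""
    dates = pd.date_range("2004-01-01", "2009-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    dose = 3.0 + 2.5 * np.cos(2 * np.pi * (doy - 172.0) / 365.25)
    loc = duvb.GeoLocation("sinusoid", 45.0, 0.0)
    return series_io.series_from_records(loc, dates, dose)


@pytest.fixture()
def noisy_sinusoid_series(sinusoid_series) -> duvb.DailyDoseSeries:
    """The sinusoid under multiplicative day-to-day (cloud-like) noise."""
    rng = np.random.default_rng(7)
    frame = sinusoid_series.frame.copy()
    frame["dose"] = frame["dose"] * rng.uniform(0.3, 1.0, len(frame))
    return sinusoid_series.with_frame(frame)
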