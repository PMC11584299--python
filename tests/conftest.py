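import numpy as np
import pandas as pd
import pytest

import fenfusion as ff
from fenfusion import dalec


@pytest.fixture(scope="session")
def site_drivers():
    """Seven-year weekly driver record of the default synthetic site."""
    return ff.generate_drivers()


@pytest.fixture(scope="session")
def truth_params():
    return ff.ProcessParameters.defaults()


@pytest.fixture(scope="session")
def truth(site_drivers):
    """Truth trajectory of the documented default parameters."""
    return ff.generate_truth(drivers=site_drivers)


@pytest.fixture(scope="session")
def observations(truth):
    return ff.sample_observations(truth, seed=1)


@pytest.fixture(scope="session")
def acm_constants():
    return ff.load_acm_constants()


@pytest.fixture
def summer_week():
    return ff.MeteoWeek(year=2014, week_index=26, doy=179.0, t_min=10.0,
                        t_max=20.0, sw_rad=18.0, precip=5.0, co2=410.0,
                        day_length=21.0)


@pytest.fixture
def winter_week():
    return ff.MeteoWeek(year=2014, week_index=2, doy=11.0, t_min=-25.0,
                        t_max=-15.0, sw_rad=0.5, precip=3.0, co2=405.0,
                        day_length=4.0)


def make_result(pools, fluxes, lai, n_years=1):
    """Fabricate a minimal SimulationResult for bookkeeping tests."""
    n = len(lai)
    weeks = (np.arange(n) % dalec.WEEKS_PER_YEAR) + 1
    years = 2014 + np.arange(n) // dalec.WEEKS_PER_YEAR
    drv = pd.DataFrame({
        "year": years, "week": weeks,
        "doy": [dalec.week_mid_doy(int(w)) for w in weeks],
        "tmin_C": 0.0, "tmax_C": 10.0, "swrad_MJm2d": 10.0,
        "precip_mm": 5.0, "co2_ppm": 400.0, "daylength_h": 12.0,
    })
    dt = np.array([dalec.week_dt(int(w)) for w in weeks])
    return dalec.SimulationResult(pools=pools, fluxes=fluxes, lai=lai,
                                  drivers=drv, dt=dt)
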