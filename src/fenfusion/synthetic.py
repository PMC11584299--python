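"""Synthetic study site: weekly drivers, truth trajectories, noisy observations.

The generator emulates the statistical structure of a seven-year weekly
record at a sub-Arctic rich fen (64.82 N): strongly seasonal temperatures
around a mean annual value of -0.95 degC, seasonal shortwave radiation,
log-normal weekly precipitation, long photoperiods from solar geometry, and
an atmospheric CO2 series that starts at 400.584 ppm in the first week and
rises so its multi-year mean is about 432 ppm.  Observation sampling adds
independent Gaussian noise at the published stream uncertainties, restricts
LAI availability to April-September, and provides alternate-year
assimilation masks.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import acm, dalec
from .calibration import ObservationSet, StockObservation, assimilation_mask

__all__ = [
    "SiteConfig",
    "ErrorModel",
    "generate_drivers",
    "generate_truth",
    "sample_observations",
]

#: ISO weeks treated as the April-September LAI availability window.
LAI_WEEKS = (14, 39)


@dataclass
class SiteConfig:
    """Geometry and climate statistics of the synthetic site."""

    latitude: float = 64.82
    n_years: int = 7
    start_year: int = 2014
    mean_annual_temp: float = -0.95      # degC
    temp_amplitude: float = 17.0         # degC, seasonal half-range
    temp_peak_doy: float = 200.0
    diurnal_range: float = 9.0           # degC between t_min and t_max
    temp_noise: float = 2.0              # degC weekly white noise
    swrad_mean: float = 10.5             # MJ m-2 d-1 annual mean
    swrad_amplitude: float = 10.0
    swrad_noise: float = 1.0
    precip_log_mean: float = 1.6         # log(mm week-1)
    precip_log_sd: float = 0.8
    co2_start: float = 400.584           # ppm, first model week
    co2_trend: float = 11.25             # ppm year-1 (site-level series)
    co2_seasonal_amplitude: float = 8.0  # ppm, winter-high cycle
    co2_noise: float = 0.0
    seed: int = 0


@dataclass
class ErrorModel:
    """Observation uncertainties of the assimilated streams."""

    nee_sigma: float = 0.58              # gC m-2 d-1
    reco_sigma: float = 1.0              # gC m-2 d-1
    lai_frac_sigma: float = 0.2          # fractional
    lai_sigma_floor: float = 0.5         # m2 m-2
    soc_sigma: float = 5000.0            # gC m-2
    fine_root_sigma: float = 140.86      # gC m-2
    aboveground_sigma: float = 49.165    # gC m-2

    def __post_init__(self):
        for f in ("nee_sigma", "reco_sigma", "lai_sigma_floor",
                  "soc_sigma", "fine_root_sigma", "aboveground_sigma"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def generate_drivers(config: SiteConfig | None = None) -> pd.DataFrame:
    """Weekly driver table for ``n_years`` model years of 52 weeks.

    Deterministic given ``config.seed``; the first-week CO2 equals
    ``co2_start`` exactly (the CO2 series carries no noise by default).
    """
    if config is None:
        config = SiteConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    doy1 = dalec.week_mid_doy(1)
    co2_phase0 = np.cos(2 * np.pi * (doy1 - 15.0) / dalec.YEAR_LENGTH)
    for y in range(config.n_years):
        for w in range(1, dalec.WEEKS_PER_YEAR + 1):
            doy = dalec.week_mid_doy(w)
            years_elapsed = y + (doy - doy1) / dalec.YEAR_LENGTH
            t_season = config.mean_annual_temp + config.temp_amplitude * np.cos(
                2 * np.pi * (doy - config.temp_peak_doy) / dalec.YEAR_LENGTH)
            t_mean = t_season + rng.normal(0.0, config.temp_noise)
            sw = config.swrad_mean + config.swrad_amplitude * np.cos(
                2 * np.pi * (doy - 172.0) / dalec.YEAR_LENGTH)
            sw = max(0.0, sw + rng.normal(0.0, config.swrad_noise))
            precip = float(rng.lognormal(config.precip_log_mean,
                                         config.precip_log_sd))
            co2_seas = config.co2_seasonal_amplitude * (
                np.cos(2 * np.pi * (doy - 15.0) / dalec.YEAR_LENGTH)
                - co2_phase0)
            co2 = (config.co2_start + config.co2_trend * years_elapsed
                   + co2_seas)
            if config.co2_noise > 0:
                co2 += rng.normal(0.0, config.co2_noise)
            rows.append({
                "year": config.start_year + y,
                "week": w,
                "doy": doy,
                "tmin_C": t_mean - 0.5 * config.diurnal_range,
                "tmax_C": t_mean + 0.5 * config.diurnal_range,
                "swrad_MJm2d": sw,
                "precip_mm": precip,
                "co2_ppm": co2,
                "daylength_h": acm.day_length(config.latitude, min(doy, 365.0)),
            })
    return pd.DataFrame(rows, columns=list(dalec.DRIVER_COLUMNS))


def generate_truth(params: dalec.ProcessParameters | None = None,
                   drivers: pd.DataFrame | None = None,
                   config: SiteConfig | None = None) -> dalec.SimulationResult:
    """Forward-run the documented truth parameters over the drivers.

    The returned result keeps the truth parameter vector attached (in
    ``result.params``) so twin-experiment recovery can be scored.  A truth
    violating the ecological constraints triggers a warning, because
    recovery experiments need constraint-feasible truths.
    """
    if params is None:
        params = dalec.ProcessParameters.defaults()
    if drivers is None:
        drivers = generate_drivers(config)
    result = dalec.simulate(params, drivers, run_id="truth")
    from .calibration import check_edcs

    ok, violated = check_edcs(params, result)
    if not ok:
        import warnings

        warnings.warn(
            f"truth parameters violate ecological constraints: {violated}",
            stacklevel=2,
        )
    return result


def sample_observations(truth: dalec.SimulationResult,
                        errors: ErrorModel | None = None,
                        seed: int = 0,
                        assimilate_years=None,
                        zero_noise: bool = False) -> ObservationSet:
    """Noisy weekly observations of NEE, Reco and LAI plus stock points.

    LAI is present only in the April-September window (ISO weeks 14-39);
    SOC and fine-root stocks constrain the initial pools and the
    aboveground stock is a single point in the first week (foliage + wood).
    With ``zero_noise`` the observation values equal the truth exactly.
    """
    if errors is None:
        errors = ErrorModel()
    rng = np.random.default_rng(seed)
    n = truth.n_weeks
    weeks = truth.drivers["week"].to_numpy(int)
    years = truth.drivers["year"].to_numpy(int)

    nee_true = truth.flux("nee")
    reco_true = truth.flux("reco")
    lai_true = truth.lai

    def noisy(vals, sig):
        if zero_noise:
            return vals.copy()
        return vals + rng.normal(0.0, 1.0, size=len(vals)) * sig

    nee_sigma = np.full(n, errors.nee_sigma)
    reco_sigma = np.full(n, errors.reco_sigma)
    lai_sigma = np.maximum(errors.lai_frac_sigma * lai_true,
                           errors.lai_sigma_floor)

    nee = noisy(nee_true, nee_sigma)
    reco = noisy(reco_true, reco_sigma)
    lai = noisy(lai_true, lai_sigma)

    present = np.ones(n, dtype=bool)
    lai_present = (weeks >= LAI_WEEKS[0]) & (weeks <= LAI_WEEKS[1])

    pools0 = truth.pools[0]
    stocks = [
        StockObservation(pool="c_som", week=0,
                         value=float(pools0[5]) if zero_noise
                         else float(pools0[5] + rng.normal(0, errors.soc_sigma)),
                         sigma=errors.soc_sigma),
        StockObservation(pool="c_root", week=0,
                         value=float(pools0[2]) if zero_noise
                         else float(pools0[2] + rng.normal(0, errors.fine_root_sigma)),
                         sigma=errors.fine_root_sigma),
        StockObservation(pool="aboveground", week=0,
                         value=float(pools0[1] + pools0[3]) if zero_noise
                         else float(pools0[1] + pools0[3]
                                    + rng.normal(0, errors.aboveground_sigma)),
                         sigma=errors.aboveground_sigma),
    ]

    mask = assimilation_mask(truth.drivers, assimilate_years)
    return ObservationSet(
        years=years, weeks=weeks,
        nee=nee, nee_sigma=nee_sigma, nee_present=present.copy(),
        reco=reco, reco_sigma=reco_sigma, reco_present=present.copy(),
        lai=lai, lai_sigma=lai_sigma, lai_present=lai_present,
        stocks=stocks, assimilate=mask,
    )
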