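"""Counterfactual driver experiments attributing productivity trends to CO2.

Two driver transforms isolate the role of rising atmospheric CO2 in the
simulated productivity trend:

* **fixed CO2** -- the CO2 column is pinned at a constant value (by default
  the first week's observed concentration, 400.584 ppm for the reference
  site) while every other driver is untouched;
* **fixed climate** -- every non-CO2 driver at (year, week) is replaced by
  the mean of that week across all years (the weekly climatology), removing
  interannual meteorological variability while the CO2 trend survives.

The calibrated posterior ensemble is re-simulated under the transformed
drivers and compared against the factual runs.  The total change in GPP is
further decomposed into the *direct* fertilisation effect (the canopy
model's response to the CO2 difference at the factual leaf area) and the
*indirect* effect mediated by the simulated LAI change; the two components
sum to the total by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel, acm, dalec
from .calibration import PosteriorEnsemble

__all__ = [
    "ExperimentSpec",
    "fixed_co2_drivers",
    "fixed_climate_drivers",
    "run_experiment",
    "decompose_co2_effect",
    "relative_change",
]

_CLIMATE_COLUMNS = ("tmin_C", "tmax_C", "swrad_MJm2d", "precip_mm",
                    "daylength_h")


@dataclass(frozen=True)
class ExperimentSpec:
    """A named driver transform."""

    name: str                       # "factual" | "fixed_co2" | "fixed_climate"
    co2_value: float | str = "first-week"
    climatology_years: tuple | None = None

    def apply(self, drivers: pd.DataFrame) -> pd.DataFrame:
        if self.name == "factual":
            return drivers.copy()
        if self.name == "fixed_co2":
            return fixed_co2_drivers(drivers, self.co2_value)
        if self.name == "fixed_climate":
            return fixed_climate_drivers(drivers)
        raise ValueError(f"unknown experiment {self.name!r}")


def fixed_co2_drivers(drivers: pd.DataFrame,
                      value: float | str = "first-week") -> pd.DataFrame:
    """Pin the CO2 column at a constant; all other columns untouched."""
    if len(drivers) == 0:
        raise ValueError("driver record is empty")
    if isinstance(value, str):
        if value != "first-week":
            raise ValueError(f"unknown CO2 value spec {value!r}")
        value = float(drivers["co2_ppm"].iloc[0])
    if value <= 0:
        raise ValueError("fixed CO2 value must be positive")
    out = drivers.copy()
    out["co2_ppm"] = float(value)
    return out


def fixed_climate_drivers(drivers: pd.DataFrame) -> pd.DataFrame:
    """Replace non-CO2 drivers by their weekly climatology across years.

    Driver (year y, week w) becomes the mean over years of week w; the CO2
    column is untouched.  The transform is idempotent.
    """
    counts = drivers.groupby("year")["week"].count()
    if counts.nunique() != 1:
        raise ValueError(
            f"ragged driver years (weeks per year: {dict(counts)}); "
            "the weekly climatology needs equal-length years")
    out = drivers.copy()
    clim = drivers.groupby("week")[list(_CLIMATE_COLUMNS)].transform("mean")
    out[list(_CLIMATE_COLUMNS)] = clim
    return out


def run_experiment(ensemble: PosteriorEnsemble, drivers: pd.DataFrame,
                   constants: acm.AcmConstants | None = None) -> list:
    """Re-simulate every ensemble member under (transformed) drivers."""
    if len(ensemble) == 0:
        raise ValueError("posterior ensemble is empty")
    if constants is None:
        constants = acm.load_acm_constants()
    results = []
    for i in range(len(ensemble)):
        params = ensemble.member_params(i)
        results.append(dalec.simulate(params, drivers, constants=constants,
                                      run_id=f"member{i}"))
    return results


def decompose_co2_effect(ensemble: PosteriorEnsemble,
                         factual_drivers: pd.DataFrame,
                         counterfactual_drivers: pd.DataFrame,
                         factual_results: list | None = None,
                         counterfactual_results: list | None = None,
                         constants: acm.AcmConstants | None = None):
    """Split the ensemble-member GPP change into direct and indirect parts.

    For each member and week, the *direct* effect is the canopy model
    evaluated at the factual LAI under factual versus counterfactual
    drivers; the *indirect* (LAI-mediated) effect is the remainder of the
    total change from the full re-simulation, so direct + indirect equals
    the total exactly.  Returns ``(direct, indirect)`` arrays of shape
    (members, weeks) holding factual-minus-counterfactual GPP differences.
    """
    if len(factual_drivers) != len(counterfactual_drivers):
        raise ValueError("factual and counterfactual drivers misaligned")
    if constants is None:
        constants = acm.load_acm_constants()
    if factual_results is None:
        factual_results = run_experiment(ensemble, factual_drivers,
                                         constants=constants)
    if counterfactual_results is None:
        counterfactual_results = run_experiment(
            ensemble, counterfactual_drivers, constants=constants)
    ac = constants.as_array()
    fmat, _ = dalec.drivers_to_matrix(factual_drivers)
    cmat, _ = dalec.drivers_to_matrix(counterfactual_drivers)
    n_m = len(ensemble)
    n_w = len(factual_drivers)
    direct = np.empty((n_m, n_w))
    indirect = np.empty((n_m, n_w))
    gi = dalec.FLUX_NAMES.index("gpp")
    for i in range(n_m):
        x = ensemble.parameters[i]
        ceff = x[ensemble.names.index("c_eff")]
        gscale = x[ensemble.names.index("gpp_scale")]
        lai_f = factual_results[i].lai
        total = factual_results[i].fluxes[:, gi] \
            - counterfactual_results[i].fluxes[:, gi]
        for t in range(n_w):
            g_f = gscale * _kernel.acm_gpp_scalar(
                lai_f[t], fmat[t, 1], fmat[t, 2], fmat[t, 3], fmat[t, 4],
                fmat[t, 5], ceff, ac)
            g_c = gscale * _kernel.acm_gpp_scalar(
                lai_f[t], cmat[t, 1], cmat[t, 2], cmat[t, 3], cmat[t, 4],
                cmat[t, 5], ceff, ac)
            direct[i, t] = g_f - g_c
        indirect[i] = total - direct[i]
    return direct, indirect


def relative_change(annual_summary: pd.DataFrame,
                    base_year: int) -> pd.DataFrame:
    """Per-year deltas of median and CI bounds against a base year.

    Expects the tidy annual-summary table (columns: year, variable, lower,
    median, upper); the base year maps to zero in every column.
    """
    years = annual_summary["year"].unique()
    if base_year not in years:
        raise ValueError(f"base year {base_year} not present "
                         f"(available: {sorted(years)})")
    out = annual_summary.copy()
    base = (annual_summary[annual_summary["year"] == base_year]
            .set_index("variable")[["lower", "median", "upper"]])
    for col in ("lower", "median", "upper"):
        out[col] = out[col] - out["variable"].map(base[col])
    return out
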