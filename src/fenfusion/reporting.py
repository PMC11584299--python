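"""Ensemble summaries, carbon-budget bookkeeping and file round-trips.

Annual summaries follow the convention of the analysis: per ensemble
member, fluxes are aggregated to annual totals (gC m-2 yr-1) and stocks /
LAI to annual means, then the 0.025 / 0.5 / 0.975 quantiles across members
give the median and the 95% credible interval.  Quantiles use linear
interpolation of order statistics (the type-7 estimator), fixed so interval
values reproduce bit-exactly.

Also here: carbon-use efficiency (NPP:GPP), pool residence times
(stock / outflux), NPP allocation fractions, an ordinary-least-squares
utility, and CSV / NetCDF readers and writers for drivers, observations,
ensembles and trajectories.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from . import dalec
from .calibration import ObservationSet, PosteriorEnsemble, StockObservation

__all__ = [
    "annual_summary",
    "cue",
    "residence_time",
    "allocation_fractions",
    "linear_fit",
    "budget_table",
    "write_drivers_csv", "read_drivers_csv",
    "write_drivers_netcdf", "read_drivers_netcdf",
    "write_observations_csv", "read_observations_csv",
    "write_ensemble_csv", "read_ensemble_csv",
    "write_results_netcdf",
    "QUANTILES",
]

#: Quantile fractions of the 95% credible interval plus the median.
QUANTILES = (0.025, 0.5, 0.975)

#: Variables included in the standard annual summary.
SUMMARY_FLUXES = ("gpp", "npp", "ra", "rh", "reco", "nee")
SUMMARY_STATES = ("lai",) + dalec.POOL_NAMES


def _member_annual(result: dalec.SimulationResult) -> pd.DataFrame:
    """Annual flux totals and state means for one trajectory."""
    years = result.drivers["year"].to_numpy(int)
    dt = result.dt
    rows = {}
    for name in SUMMARY_FLUXES:
        series = result.flux(name) * dt
        rows[name] = pd.Series(series).groupby(years).sum()
    rows["lai"] = pd.Series(result.lai).groupby(years).mean()
    for i, name in enumerate(dalec.POOL_NAMES):
        rows[name] = pd.Series(result.pools[1:, i]).groupby(years).mean()
    return pd.DataFrame(rows)


def annual_summary(results: list,
                   quantiles=QUANTILES) -> pd.DataFrame:
    """Quantile summary of annual values across ensemble trajectories.

    Returns a tidy frame with columns year, variable, lower, median, upper.
    """
    if len(results) < 2:
        raise ValueError("annual summary needs at least two ensemble members")
    lo_q, med_q, hi_q = quantiles
    per_member = [_member_annual(r) for r in results]
    stacked = {v: np.stack([m[v].to_numpy() for m in per_member])
               for v in per_member[0].columns}
    years = per_member[0].index.to_numpy()
    records = []
    for v, arr in stacked.items():
        lo = np.quantile(arr, lo_q, axis=0)
        med = np.quantile(arr, med_q, axis=0)
        hi = np.quantile(arr, hi_q, axis=0)
        for j, y in enumerate(years):
            records.append({"year": int(y), "variable": v,
                            "lower": lo[j], "median": med[j], "upper": hi[j]})
    return pd.DataFrame(records)


def cue(annual_npp: float, annual_gpp: float) -> float:
    """Carbon use efficiency, the NPP:GPP ratio."""
    if annual_gpp <= 0:
        raise ValueError("CUE is undefined for non-positive GPP")
    return annual_npp / annual_gpp


def residence_time(mean_stock: float, mean_outflux: float) -> float:
    """Mean residence time (years) = mean stock / mean annual outflux.

    Returns NaN (reported as missing, never infinity) when the outflux is
    not positive.
    """
    if mean_outflux <= 0:
        return float("nan")
    return mean_stock / mean_outflux


#: Outflux flux names feeding each pool's residence time.
_POOL_OUTFLUXES = {
    "c_lab": ("labile_release",),
    "c_fol": ("leaf_fall",),
    "c_root": ("root_mort",),
    "c_wood": ("wood_mort",),
    "c_lit": ("rh_lit", "dec_lit2som"),
    "c_som": ("rh_som",),
}


def residence_time_summary(results: list,
                           quantiles=QUANTILES) -> pd.DataFrame:
    """Per-pool residence times across members, with quantile summary."""
    records = []
    for pool, outfluxes in _POOL_OUTFLUXES.items():
        i = dalec.POOL_NAMES.index(pool)
        per_member = []
        for r in results:
            stock = r.pools[1:, i].mean()
            out_per_day = sum(r.flux(f) * r.dt for f in outfluxes).sum()
            years = r.dt.sum() / dalec.YEAR_LENGTH
            per_member.append(residence_time(stock, out_per_day / years))
        vals = np.array(per_member)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            records.append({"pool": pool, "lower": np.nan, "median": np.nan,
                            "upper": np.nan})
            continue
        records.append({
            "pool": pool,
            "lower": np.quantile(vals, quantiles[0]),
            "median": np.quantile(vals, quantiles[1]),
            "upper": np.quantile(vals, quantiles[2]),
        })
    return pd.DataFrame(records)


def allocation_fractions(results: list) -> pd.DataFrame:
    """Per-member fractions of NPP reaching foliage, wood and fine root.

    Foliage counts direct allocation plus the labile-bound share (which is
    released to foliage at leaf flush), so the three fractions partition
    NPP exactly.
    """
    records = []
    for r in results:
        npp = (r.flux("npp") * r.dt).sum()
        if npp <= 0:
            raise ValueError("allocation fractions undefined for zero NPP")
        fol = ((r.flux("alloc_fol") + r.flux("alloc_lab")) * r.dt).sum() / npp
        wood = (r.flux("alloc_wood") * r.dt).sum() / npp
        root = (r.flux("alloc_root") * r.dt).sum() / npp
        records.append({"foliage": fol, "wood": wood, "fine_root": root})
    return pd.DataFrame(records)


def linear_fit(x, y) -> dict:
    """Ordinary least squares of y on x with the standard diagnostics.

    Returns slope, intercept, r2_adj, p_value (two-sided t-test on the
    slope) and residual_se.  Requires n >= 3 so the adjusted R-squared is
    defined.
    """
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("singular design: x is constant")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    residual_se = float(np.sqrt(ss_res / (n - 2)))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2_adj": float(r2_adj),
        "p_value": float(res.pvalue),
        "residual_se": residual_se,
    }


def budget_table(results: list) -> pd.DataFrame:
    """Whole-run carbon-budget table: median and 95% CI per flux and stock.

    Fluxes are mean annual totals (gC m-2 yr-1), stocks are run means
    (gC m-2), plus carbon-use efficiency per member.  The flux identities
    (NPP = GPP - Ra, Reco = Ra + Rh, NEE = Reco - GPP) hold for every
    member at the annual scale by construction.
    """
    years_len = results[0].dt.sum() / dalec.YEAR_LENGTH
    rows = {}
    for name in dalec.FLUX_NAMES:
        vals = np.array([(r.flux(name) * r.dt).sum() / years_len
                         for r in results])
        rows[name] = vals
    for i, name in enumerate(dalec.POOL_NAMES):
        rows[name] = np.array([r.pools[1:, i].mean() for r in results])
    rows["cue"] = rows["npp"] / rows["gpp"]
    records = []
    for name, vals in rows.items():
        records.append({
            "quantity": name,
            "lower": np.quantile(vals, QUANTILES[0]),
            "median": np.quantile(vals, QUANTILES[1]),
            "upper": np.quantile(vals, QUANTILES[2]),
        })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# file round-trips


def write_drivers_csv(drivers: pd.DataFrame, path) -> None:
    drivers.to_csv(path, index=False)


def read_drivers_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in dalec.DRIVER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"driver CSV missing columns: {missing}")
    return df


def write_drivers_netcdf(drivers: pd.DataFrame, path) -> None:
    import xarray as xr

    ds = xr.Dataset({c: ("time", drivers[c].to_numpy())
                     for c in dalec.DRIVER_COLUMNS},
                    coords={"time": np.arange(len(drivers))})
    ds.to_netcdf(path, engine="scipy")


def read_drivers_netcdf(path) -> pd.DataFrame:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        return pd.DataFrame({c: ds[c].to_numpy()
                             for c in dalec.DRIVER_COLUMNS})


def _week_start(year: int, week: int) -> str:
    d = _dt.date(int(year), 1, 1) + _dt.timedelta(days=7 * (int(week) - 1))
    return d.isoformat()


def write_observations_csv(obs: ObservationSet, path) -> None:
    """Tidy observation CSV: week_start, stream, value, sigma.

    Stock rows use stream names ``stock:<pool>``; absent weekly points are
    omitted.  The assimilation mask is derivable from configuration (the
    assimilated-year list), not stored.
    """
    records = []
    for stream, vals, sigs, present in (
            ("nee", obs.nee, obs.nee_sigma, obs.nee_present),
            ("reco", obs.reco, obs.reco_sigma, obs.reco_present),
            ("lai", obs.lai, obs.lai_sigma, obs.lai_present)):
        for i in range(obs.n_weeks):
            if present[i]:
                records.append({
                    "week_start": _week_start(obs.years[i], obs.weeks[i]),
                    "stream": stream,
                    "value": vals[i],
                    "sigma": sigs[i],
                })
    for s in obs.stocks:
        i = min(s.week, obs.n_weeks - 1)
        records.append({
            "week_start": _week_start(obs.years[i], obs.weeks[i]),
            "stream": f"stock:{s.pool}",
            "value": s.value,
            "sigma": s.sigma,
        })
    pd.DataFrame(records).to_csv(path, index=False)


def read_observations_csv(path, drivers: pd.DataFrame,
                          assimilate_years=None) -> ObservationSet:
    """Rebuild an ObservationSet against a driver record's week grid."""
    from .calibration import assimilation_mask

    df = pd.read_csv(path)
    n = len(drivers)
    starts = [_week_start(y, w) for y, w in
              zip(drivers["year"], drivers["week"])]
    index = {s: i for i, s in enumerate(starts)}
    series = {}
    for stream in ("nee", "reco", "lai"):
        vals = np.full(n, np.nan)
        sigs = np.ones(n)
        present = np.zeros(n, dtype=bool)
        sub = df[df["stream"] == stream]
        for _, row in sub.iterrows():
            i = index[row["week_start"]]
            vals[i] = row["value"]
            sigs[i] = row["sigma"]
            present[i] = True
        vals[~present] = 0.0
        series[stream] = (vals, sigs, present)
    stocks = []
    for _, row in df[df["stream"].str.startswith("stock:")].iterrows():
        stocks.append(StockObservation(
            pool=row["stream"].split(":", 1)[1],
            week=index[row["week_start"]],
            value=float(row["value"]), sigma=float(row["sigma"])))
    return ObservationSet(
        years=drivers["year"].to_numpy(int),
        weeks=drivers["week"].to_numpy(int),
        nee=series["nee"][0], nee_sigma=series["nee"][1],
        nee_present=series["nee"][2],
        reco=series["reco"][0], reco_sigma=series["reco"][1],
        reco_present=series["reco"][2],
        lai=series["lai"][0], lai_sigma=series["lai"][1],
        lai_present=series["lai"][2],
        stocks=stocks,
        assimilate=assimilation_mask(drivers, assimilate_years),
    )


def write_ensemble_csv(ensemble: PosteriorEnsemble, path) -> None:
    ensemble.to_frame().to_csv(path, index=False)


def read_ensemble_csv(path) -> PosteriorEnsemble:
    df = pd.read_csv(path)
    names = tuple(c for c in df.columns if c not in ("chain", "log_posterior"))
    return PosteriorEnsemble(
        parameters=df[list(names)].to_numpy(float),
        chain_ids=df["chain"].to_numpy(int),
        log_posteriors=df["log_posterior"].to_numpy(float),
        names=names,
    )


def write_results_netcdf(results: list, path) -> None:
    """Stack ensemble trajectories into one NetCDF (member, time)."""
    import xarray as xr

    n_m = len(results)
    n_t = results[0].n_weeks
    data = {}
    for name in dalec.FLUX_NAMES:
        data[name] = (("member", "time"),
                      np.stack([r.flux(name) for r in results]))
    for i, name in enumerate(dalec.POOL_NAMES):
        data[name] = (("member", "time"),
                      np.stack([r.pools[1:, i] for r in results]))
    data["lai"] = (("member", "time"), np.stack([r.lai for r in results]))
    ds = xr.Dataset(data, coords={
        "member": np.arange(n_m),
        "time": np.arange(n_t),
        "year": ("time", results[0].drivers["year"].to_numpy()),
        "week": ("time", results[0].drivers["week"].to_numpy()),
    })
    ds.to_netcdf(path, engine="scipy")
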