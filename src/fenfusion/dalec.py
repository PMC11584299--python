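"""Six-pool terrestrial carbon mass-balance model at a weekly time step.

The model tracks four live pools (labile, foliage, fine root, wood /
structural) and two dead pools (litter, soil organic matter).  Each week:

* GPP is computed by the canopy submodel (:mod:`fenfusion.acm`) from
  LAI = c_fol / LMA and the week's meteorology;
* a fixed fraction ``f_auto`` of GPP is respired autotrophically, the
  remainder (NPP) is allocated to labile, foliage, fine root and wood by
  fixed fractions (wood receives the residual);
* leaf flush (labile -> foliage) and senescence (foliage -> litter) follow a
  wrapped-Gaussian day-of-year phenology with a survival-exponent release
  rule, so the configured annual completeness fractions are honoured
  exactly;
* fine-root mortality feeds litter, wood mortality feeds SOM directly;
* litter mineralisation, litter -> SOM decomposition and SOM mineralisation
  are first-order rates scaled by an exponential temperature function.

Pool losses are discrete per-step fractions ``min(1, rate * f_T * dt)`` of
the start-of-step pool, so pools cannot go negative and carbon is conserved
to machine precision: the change in total carbon equals
``(GPP - Ra - Rh) * dt`` each step.

The calendar is a 365.25-day year split into 52 weeks of 7 days, with week
52 absorbing the remainder (8.25 days); day-of-year is taken mid-week.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from . import _kernel, acm

__all__ = [
    "CarbonPools",
    "ProcessParameters",
    "MeteoWeek",
    "FluxWeek",
    "SimulationResult",
    "ParameterRegistry",
    "load_registry",
    "temperature_rate_modifier",
    "phenology_weights",
    "release_fraction",
    "step",
    "simulate",
    "lai_from_foliage",
    "mass_balance_residual",
    "week_dt",
    "week_mid_doy",
    "drivers_to_matrix",
    "DRIVER_COLUMNS",
    "POOL_NAMES",
    "FLUX_NAMES",
]

POOL_NAMES = ("c_lab", "c_fol", "c_root", "c_wood", "c_lit", "c_som")

FLUX_NAMES = (
    "gpp", "ra", "npp",
    "alloc_lab", "alloc_fol", "alloc_root", "alloc_wood",
    "labile_release", "leaf_fall", "root_mort", "wood_mort",
    "dec_lit2som", "rh_lit", "rh_som", "rh", "reco", "nee", "nbe",
)

DRIVER_COLUMNS = (
    "year", "week", "doy", "tmin_C", "tmax_C",
    "swrad_MJm2d", "precip_mm", "co2_ppm", "daylength_h",
)

DAYS_PER_YEAR = 365
YEAR_LENGTH = 365.25
WEEKS_PER_YEAR = 52


def week_dt(week: int) -> float:
    """Length of a model week in days (week 52 absorbs the year remainder)."""
    if not 1 <= week <= WEEKS_PER_YEAR:
        raise ValueError(f"week must be 1..52, got {week}")
    if week == WEEKS_PER_YEAR:
        return YEAR_LENGTH - 7.0 * (WEEKS_PER_YEAR - 1)
    return 7.0


def week_mid_doy(week: int) -> float:
    """Mid-week day of year for a model week."""
    if week == WEEKS_PER_YEAR:
        return 0.5 * (358 + YEAR_LENGTH)
    return 7.0 * (week - 1) + 4.0


@dataclass
class CarbonPools:
    """The six model carbon stocks at one instant (gC m-2)."""

    c_lab: float
    c_fol: float
    c_root: float
    c_wood: float
    c_lit: float
    c_som: float

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"pool {f.name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_lab, self.c_fol, self.c_root,
                         self.c_wood, self.c_lit, self.c_som])

    @classmethod
    def from_array(cls, a) -> "CarbonPools":
        return cls(*(float(v) for v in a))

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


@dataclass
class MeteoWeek:
    """One week of forcing: temperatures, radiation, precipitation, CO2."""

    year: int
    week_index: int
    doy: float
    t_min: float
    t_max: float
    sw_rad: float
    precip: float
    co2: float
    day_length: float

    def __post_init__(self):
        if self.t_max < self.t_min:
            raise ValueError("t_max must be >= t_min")
        if self.sw_rad < 0:
            raise ValueError("shortwave radiation must be >= 0")
        if self.co2 <= 0:
            raise ValueError("CO2 must be positive")
        if not 0 <= self.day_length <= 24:
            raise ValueError("day length must lie in [0, 24] h")


@dataclass
class FluxWeek:
    """Per-day carbon fluxes valid over one weekly step (gC m-2 d-1)."""

    gpp: float
    ra: float
    npp: float
    alloc_lab: float
    alloc_fol: float
    alloc_root: float
    alloc_wood: float
    labile_release: float
    leaf_fall: float
    root_mort: float
    wood_mort: float
    dec_lit2som: float
    rh_lit: float
    rh_som: float
    rh: float
    reco: float
    nee: float
    nbe: float

    @classmethod
    def from_array(cls, a) -> "FluxWeek":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class ParameterRegistry:
    """The ordered set of calibrated quantities with bounds and scales.

    The registry is loaded from YAML so the identity of the auxiliary
    quantities (and any prior range) can be changed without touching code.
    The shipped registry defines 28 free quantities: 18 core process
    parameters, 4 auxiliaries and the 6 initial pools.
    """

    names: tuple
    lows: np.ndarray
    highs: np.ndarray
    log_scale: np.ndarray
    defaults: np.ndarray
    descriptions: tuple

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Map a parameter vector to the unit hypercube of the priors."""
        x = np.asarray(x, dtype=float)
        safe_lo = np.where(self.log_scale, self.lows, 1.0)
        safe_hi = np.where(self.log_scale, self.highs, 1.0)
        log_span = np.where(self.log_scale,
                            np.log(safe_hi) - np.log(safe_lo), 1.0)
        return np.where(
            self.log_scale,
            (np.log(np.clip(x, 1e-300, None)) - np.log(safe_lo)) / log_span,
            (x - self.lows) / (self.highs - self.lows),
        )

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        safe_lo = np.where(self.log_scale, self.lows, 1.0)
        safe_hi = np.where(self.log_scale, self.highs, 1.0)
        return np.where(
            self.log_scale,
            np.exp(np.log(safe_lo) + u * (np.log(safe_hi) - np.log(safe_lo))),
            self.lows + u * (self.highs - self.lows),
        )


def load_registry(path=None) -> ParameterRegistry:
    """Load the calibrated-quantity registry (default: the shipped one)."""
    if path is None:
        raw = resources.files("fenfusion.data").joinpath("parameters.yaml").read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
    doc = yaml.safe_load(raw)["registry"]
    return ParameterRegistry(
        names=tuple(e["name"] for e in doc),
        lows=np.array([float(e["low"]) for e in doc]),
        highs=np.array([float(e["high"]) for e in doc]),
        log_scale=np.array([e["scale"] == "log" for e in doc]),
        defaults=np.array([float(e["default"]) for e in doc]),
        descriptions=tuple(e.get("description", "") for e in doc),
    )


_REGISTRY = None


def default_registry() -> ParameterRegistry:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    return _REGISTRY


@dataclass
class ProcessParameters:
    """The 28 calibrated quantities of the model.

    Core process parameters, four auxiliaries (separate litter temperature
    sensitivity, whole-canopy GPP scalar, phenology completeness cap,
    labile release lag) and the six initial pool sizes.  Field order
    matches the registry / kernel parameter-vector layout.
    """

    f_auto: float = 0.48
    f_fol: float = 0.25
    f_lab: float = 0.25
    f_root: float = 0.20
    d_onset: float = 140.0
    r_onset: float = 21.0
    big_f_onset: float = 0.95
    d_fall: float = 260.0
    r_fall: float = 28.0
    big_f_fall: float = 0.95
    t_root: float = 6.5e-4
    t_wood: float = 5.5e-4
    r_lit: float = 4.0e-3
    d_lit2som: float = 1.5e-4
    r_som: float = 3.0e-6
    theta: float = 0.08
    theta_lit: float = 0.08
    c_eff: float = 12.8
    lma: float = 60.0
    gpp_scale: float = 1.0
    release_cap: float = 0.99
    onset_lag: float = 7.0
    c_lab0: float = 70.0
    c_fol0: float = 5.0
    c_root0: float = 247.06
    c_wood0: float = 282.0
    c_lit0: float = 100.0
    c_som0: float = 64055.0

    def __post_init__(self):
        for name in ("f_auto", "f_fol", "f_lab", "f_root"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.f_fol + self.f_lab + self.f_root > 1:
            raise ValueError("allocation fractions f_fol + f_lab + f_root exceed 1")
        for name in ("t_root", "t_wood", "r_lit", "d_lit2som", "r_som",
                     "r_onset", "r_fall", "lma", "c_eff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in dc_fields(self)])

    @classmethod
    def from_vector(cls, x) -> "ProcessParameters":
        names = [f.name for f in dc_fields(cls)]
        return cls(**{n: float(v) for n, v in zip(names, x)})

    @classmethod
    def defaults(cls) -> "ProcessParameters":
        return cls()

    @property
    def initial_pools(self) -> CarbonPools:
        return CarbonPools(self.c_lab0, self.c_fol0, self.c_root0,
                           self.c_wood0, self.c_lit0, self.c_som0)

    @classmethod
    def n_free(cls) -> int:
        return len(dc_fields(cls))


@dataclass
class SimulationResult:
    """Aligned pool, flux and LAI trajectories from one forward run."""

    pools: np.ndarray          # (n+1, 6) -- initial state first
    fluxes: np.ndarray         # (n, 18)
    lai: np.ndarray            # (n,)
    drivers: pd.DataFrame
    dt: np.ndarray             # (n,) days
    params: ProcessParameters | None = None
    clamped: bool = False
    run_id: str = ""

    def __post_init__(self):
        n = len(self.lai)
        if self.pools.shape != (n + 1, 6) or self.fluxes.shape[0] != n:
            raise ValueError("pool/flux/LAI trajectory lengths disagree")

    @property
    def n_weeks(self) -> int:
        return len(self.lai)

    def pools_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pools[1:], columns=POOL_NAMES,
                            index=self.drivers.index)

    def fluxes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fluxes, columns=FLUX_NAMES,
                            index=self.drivers.index)

    def flux(self, name: str) -> np.ndarray:
        return self.fluxes[:, FLUX_NAMES.index(name)]

    def to_dataset(self):
        """Bundle the trajectories into an xarray Dataset (time dimension)."""
        import xarray as xr

        data = {name: ("time", self.fluxes[:, i])
                for i, name in enumerate(FLUX_NAMES)}
        for i, name in enumerate(POOL_NAMES):
            data[name] = ("time", self.pools[1:, i])
        data["lai"] = ("time", self.lai)
        data["dt_days"] = ("time", self.dt)
        coords = {
            "time": np.arange(self.n_weeks),
            "year": ("time", self.drivers["year"].to_numpy()),
            "week": ("time", self.drivers["week"].to_numpy()),
        }
        return xr.Dataset(data, coords=coords,
                          attrs={"run_id": self.run_id})


def temperature_rate_modifier(theta: float, t_mean: float) -> float:
    """Exponential temperature factor exp(theta * T) on decomposition rates."""
    if not (np.isfinite(theta) and np.isfinite(t_mean)):
        raise ValueError("temperature modifier inputs must be finite")
    return float(np.exp(theta * t_mean))


def phenology_weights(d_center: float, width: float,
                      n_days: int = DAYS_PER_YEAR) -> np.ndarray:
    """Daily phenology weights: a wrapped Gaussian bell summing to 1."""
    if width <= 0:
        raise ValueError("phenology width must be positive")
    if not 1 <= d_center <= YEAR_LENGTH:
        raise ValueError(f"phenology centre must lie in [1, {YEAR_LENGTH}]")
    return _kernel.phenology_daily_weights(float(d_center), float(width),
                                           int(n_days))


def release_fraction(completeness: float, weight_sum_over_step: float) -> float:
    """Per-step released fraction under the survival-exponent rule.

    ``1 - (1 - completeness) ** weight_sum`` guarantees that, with inflows
    disabled, the survival fractions over a full year multiply to exactly
    ``1 - completeness``.
    """
    if not 0 <= completeness < 1:
        raise ValueError("completeness must lie in [0, 1); cap it below 1")
    if not 0 <= weight_sum_over_step <= 1:
        raise ValueError("weight sum over a step must lie in [0, 1]")
    return 1.0 - (1.0 - completeness) ** weight_sum_over_step


def lai_from_foliage(c_fol: float, lma: float) -> float:
    """Leaf area index from foliage carbon and leaf mass per area."""
    if lma <= 0:
        raise ValueError("leaf mass per area must be positive")
    return c_fol / lma


def _met_to_row(met: MeteoWeek, dt: float) -> np.ndarray:
    return np.array([met.doy, met.t_min, met.t_max, met.sw_rad,
                     met.co2, met.day_length, dt])


def step(pools: CarbonPools, params: ProcessParameters, met: MeteoWeek,
         dt: float | None = None,
         constants: acm.AcmConstants | None = None):
    """Advance the pools by one week; returns ``(new_pools, FluxWeek)``."""
    if dt is None:
        dt = week_dt(met.week_index)
    if constants is None:
        constants = acm.load_acm_constants()
    x = params.as_vector().copy()
    x[22:28] = pools.as_array()
    row = _met_to_row(met, dt)
    pool_tr, flux_tr, _, _ = _python_step(x, row, met.week_index,
                                          constants.as_array())
    new = CarbonPools.from_array(pool_tr[1])
    return new, FluxWeek.from_array(flux_tr[0])


def _python_step(x, row, week, ac):
    """Reference single-step update (mirrors the kernel arithmetic)."""
    doy, tmin, tmax, swrad, co2, dayl, dt = row
    tmean = 0.5 * (tmin + tmax)
    c = x[22:28].copy()
    cap = x[20]
    f_on = min(x[6], cap)
    f_fall = min(x[9], cap)
    onset_center = x[4] + x[21]
    if onset_center > DAYS_PER_YEAR:
        onset_center -= DAYS_PER_YEAR
    onset_w = _kernel.weekly_weight_sums(onset_center, x[5])[week - 1]
    fall_w = _kernel.weekly_weight_sums(x[7], x[8])[week - 1]

    lai = c[1] / x[18]
    gpp = x[19] * _kernel.acm_gpp_scalar(lai, tmin, tmax, swrad, co2, dayl,
                                         x[17], ac)
    ra = x[0] * gpp
    npp = gpp - ra
    al = np.array([x[2], x[1], x[3], 1.0 - x[1] - x[2] - x[3]]) * npp

    lab_release = release_fraction(f_on, onset_w) * c[0]
    leaf_fall = release_fraction(f_fall, fall_w) * c[1]
    ft = np.exp(x[15] * tmean)
    ft_lit = np.exp(x[16] * tmean)
    root_mort = min(1.0, x[10] * dt) * c[2]
    wood_mort = min(1.0, x[11] * dt) * c[3]
    lit_frac = min(1.0, (x[12] + x[13]) * ft_lit * dt)
    lit_loss = lit_frac * c[4]
    rh_lit = lit_loss * x[12] / (x[12] + x[13]) if x[12] + x[13] > 0 else 0.0
    lit2som = lit_loss - rh_lit
    rh_som = min(1.0, x[14] * ft * dt) * c[5]

    new = np.array([
        c[0] - lab_release + al[0] * dt,
        c[1] - leaf_fall + al[1] * dt + lab_release,
        c[2] - root_mort + al[2] * dt,
        c[3] - wood_mort + al[3] * dt,
        c[4] - lit_loss + leaf_fall + root_mort,
        c[5] - rh_som + lit2som + wood_mort,
    ])
    clamped = bool((new < 0).any())
    new = np.clip(new, 0.0, None)
    rh = (rh_lit + rh_som) / dt if dt > 0 else 0.0
    fluxes = np.array([[
        gpp, ra, npp, al[0], al[1], al[2], al[3],
        lab_release / dt if dt > 0 else 0.0,
        leaf_fall / dt if dt > 0 else 0.0,
        root_mort / dt if dt > 0 else 0.0,
        wood_mort / dt if dt > 0 else 0.0,
        lit2som / dt if dt > 0 else 0.0,
        rh_lit / dt if dt > 0 else 0.0,
        rh_som / dt if dt > 0 else 0.0,
        rh, ra + rh, ra + rh - gpp, ra + rh - gpp,
    ]])
    pools = np.vstack([c, new])
    return pools, fluxes, np.array([lai]), clamped


def drivers_to_matrix(drivers: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Convert a driver table to the kernel matrix; returns (matrix, dt)."""
    missing = [c for c in DRIVER_COLUMNS if c not in drivers.columns]
    if missing:
        raise ValueError(f"driver table missing columns: {missing}")
    dt = np.array([week_dt(int(w)) for w in drivers["week"]])
    mat = np.column_stack([
        drivers["doy"].to_numpy(float),
        drivers["tmin_C"].to_numpy(float),
        drivers["tmax_C"].to_numpy(float),
        drivers["swrad_MJm2d"].to_numpy(float),
        drivers["co2_ppm"].to_numpy(float),
        drivers["daylength_h"].to_numpy(float),
        dt,
    ])
    return mat, dt


def _check_contiguous(drivers: pd.DataFrame):
    weeks = drivers["week"].to_numpy(int)
    years = drivers["year"].to_numpy(int)
    if weeks[0] != 1:
        raise ValueError("driver record must start at week 1")
    for i in range(1, len(weeks)):
        expect_w = weeks[i - 1] % WEEKS_PER_YEAR + 1
        expect_y = years[i - 1] + (1 if weeks[i - 1] == WEEKS_PER_YEAR else 0)
        if weeks[i] != expect_w or years[i] != expect_y:
            raise ValueError(
                f"driver record has a gap at row {i}: expected "
                f"year {expect_y} week {expect_w}, found "
                f"year {years[i]} week {weeks[i]}"
            )


def simulate(params: ProcessParameters, drivers: pd.DataFrame,
             init: CarbonPools | None = None,
             constants: acm.AcmConstants | None = None,
             run_id: str = "") -> SimulationResult:
    """Run the model over a contiguous weekly driver record.

    ``init`` overrides the initial pools carried by ``params``.  The run is
    deterministic: identical inputs give bitwise-identical trajectories.
    """
    if len(drivers) == 0:
        raise ValueError("driver record is empty")
    _check_contiguous(drivers)
    if constants is None:
        constants = acm.load_acm_constants()
    x = params.as_vector().copy()
    if init is not None:
        x[22:28] = init.as_array()
    mat, dt = drivers_to_matrix(drivers)
    pools, fluxes, lai, clamped = _kernel.simulate_kernel(
        x, mat, constants.as_array())
    return SimulationResult(pools=pools, fluxes=fluxes, lai=lai,
                            drivers=drivers.reset_index(drop=True), dt=dt,
                            params=params, clamped=bool(clamped),
                            run_id=run_id)


def mass_balance_residual(result: SimulationResult) -> np.ndarray:
    """Per-step conservation residual (gC m-2).

    ``residual_t = delta(total C) - (gpp - ra - rh)_t * dt`` -- zero to
    round-off for any trajectory produced by :func:`simulate`.
    """
    total = result.pools.sum(axis=1)
    net = (result.fluxes[:, _kernel.F_GPP]
           - result.fluxes[:, _kernel.F_RA]
           - result.fluxes[:, _kernel.F_RH])
    return np.diff(total) - net * result.dt
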