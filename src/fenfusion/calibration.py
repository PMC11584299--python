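"""Bayesian model-data fusion: priors, likelihood, constraints, AP-MCMC.

Calibration samples the 28 free quantities against weekly NEE, Reco and LAI
observations plus sparse carbon-stock points, under uniform (or
log-uniform) priors and a set of ecological and dynamical constraints
(EDCs) that reject implausible or unstable parameter sets outright.  The
sampler is an adaptive-proposal Metropolis algorithm: the jump covariance
is re-estimated from the chain history at a fixed interval and the global
scale is tuned toward the standard multivariate acceptance target.  Three
independent chains are run by default and 100 evenly spaced subsamples per
chain are pooled into the 300-member posterior ensemble that underlies all
credible-interval summaries.

Each observation stream's Gaussian log-likelihood is multiplied by a
square-root normalisation factor of 0.5, which tempers the large volume of
flux data against the sparse stock observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel, acm, dalec

__all__ = [
    "ObservationSet",
    "StockObservation",
    "PriorSpec",
    "EdcConfig",
    "McmcConfig",
    "McmcChains",
    "PosteriorEnsemble",
    "assimilation_mask",
    "log_likelihood",
    "log_prior",
    "check_edcs",
    "propose",
    "run_mcmc",
    "extract_ensemble",
    "load_config",
    "DEFAULT_ASSIMILATE_YEARS",
    "SQRT_NORMALISATION",
]

#: Alternate years whose flux/LAI data enter the likelihood; the others are
#: held out for validation.
DEFAULT_ASSIMILATE_YEARS = (2014, 2016, 2018, 2020)

#: Square-root likelihood normalisation: each stream's Gaussian log-misfit
#: is halved, i.e. the likelihood is raised to the power 1/2.
SQRT_NORMALISATION = 0.5

_POOL_INDEX = {name: i for i, name in enumerate(dalec.POOL_NAMES)}
_POOL_INDEX["aboveground"] = -1  # foliage + wood at the named week


@dataclass
class StockObservation:
    """A sparse carbon-stock observation tied to one pool and week."""

    pool: str
    week: int            # index into the pool trajectory (0 = initial state)
    value: float
    sigma: float

    def __post_init__(self):
        if self.pool not in _POOL_INDEX:
            raise ValueError(f"unknown pool {self.pool!r}")
        if self.sigma <= 0:
            raise ValueError("stock sigma must be positive")


@dataclass
class ObservationSet:
    """Weekly NEE/Reco/LAI series with uncertainties, masks and stocks.

    The LAI uncertainty floor (default 0.5 m2 m-2) is enforced on
    construction, representing model-structural uncertainty in the
    foliage-to-LAI mapping.
    """

    years: np.ndarray
    weeks: np.ndarray
    nee: np.ndarray
    nee_sigma: np.ndarray
    nee_present: np.ndarray
    reco: np.ndarray
    reco_sigma: np.ndarray
    reco_present: np.ndarray
    lai: np.ndarray
    lai_sigma: np.ndarray
    lai_present: np.ndarray
    stocks: list = field(default_factory=list)
    assimilate: np.ndarray | None = None
    lai_sigma_floor: float = 0.5

    def __post_init__(self):
        n = len(self.years)
        for name in ("weeks", "nee", "nee_sigma", "nee_present",
                     "reco", "reco_sigma", "reco_present",
                     "lai", "lai_sigma", "lai_present"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"observation series {name} misaligned "
                                 f"({len(getattr(self, name))} vs {n} weeks)")
        for name in ("nee_sigma", "reco_sigma"):
            if (getattr(self, name) <= 0).any():
                raise ValueError(f"{name} must be positive everywhere")
        self.lai_sigma = np.maximum(np.asarray(self.lai_sigma, float),
                                    self.lai_sigma_floor)
        if self.assimilate is None:
            self.assimilate = np.ones(n, dtype=bool)
        elif len(self.assimilate) != n:
            raise ValueError("assimilation mask misaligned with weeks")

    @property
    def n_weeks(self) -> int:
        return len(self.years)


def assimilation_mask(drivers: pd.DataFrame,
                      assimilate_years=None) -> np.ndarray:
    """Boolean mask: True for weeks whose calendar year is assimilated."""
    if assimilate_years is None:
        assimilate_years = DEFAULT_ASSIMILATE_YEARS
    years = drivers["year"].to_numpy(int)
    return np.isin(years, list(assimilate_years))


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform / log-uniform priors over the free quantities."""

    names: tuple
    lows: np.ndarray
    highs: np.ndarray
    log_scale: np.ndarray

    def __post_init__(self):
        if (self.lows >= self.highs).any():
            raise ValueError("every prior needs lower < upper")
        if (self.log_scale & (self.lows <= 0)).any():
            raise ValueError("log-uniform priors require a positive lower bound")

    def __len__(self):
        return len(self.names)

    @classmethod
    def from_registry(cls, registry: dalec.ParameterRegistry | None = None
                      ) -> "PriorSpec":
        if registry is None:
            registry = dalec.default_registry()
        return cls(names=registry.names, lows=registry.lows.copy(),
                   highs=registry.highs.copy(),
                   log_scale=registry.log_scale.copy())

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
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
        u = np.asarray(u, float)
        safe_lo = np.where(self.log_scale, self.lows, 1.0)
        safe_hi = np.where(self.log_scale, self.highs, 1.0)
        return np.where(
            self.log_scale,
            np.exp(np.log(safe_lo) + u * (np.log(safe_hi) - np.log(safe_lo))),
            self.lows + u * (self.highs - self.lows),
        )


@dataclass
class EdcConfig:
    """Ecological and dynamical constraint registry with per-rule switches.

    E1: SOM mineralises slower than litter (r_som < r_lit).
    E2: fine roots turn over faster than wood (t_root > t_wood).
    E3: quasi-steady pools -- no pool may grow or shrink by more than
        ``growth_bound``-fold between the start and end of the run.
    E4: no negative-pool clamping occurred during the run.
    E5: the autotrophic fraction lies in a plausible range.
    """

    enable: dict = field(default_factory=lambda: {
        "E1": True, "E2": True, "E3": True, "E4": True, "E5": True})
    growth_bound: float = 10.0
    f_auto_range: tuple = (0.2, 0.8)


EDC_IDS = ("E1", "E2", "E3", "E4", "E5")


def check_edcs(params, result: dalec.SimulationResult,
               config: EdcConfig | None = None):
    """Evaluate every enabled constraint; returns (ok, violated ids)."""
    if config is None:
        config = EdcConfig()
    x = params.as_vector() if hasattr(params, "as_vector") else np.asarray(params)
    mask = _kernel.check_edcs_kernel(
        x, result.pools, result.clamped,
        config.growth_bound, config.f_auto_range[0], config.f_auto_range[1])
    violated = [EDC_IDS[i] for i in range(len(EDC_IDS))
                if (mask >> i) & 1 and config.enable.get(EDC_IDS[i], True)]
    return (len(violated) == 0), violated


def _obs_arrays(obs: ObservationSet):
    """Flatten an ObservationSet into the kernel's array arguments."""
    use = obs.assimilate.astype(bool)
    stock_pool = np.array([_POOL_INDEX[s.pool] for s in obs.stocks],
                          dtype=np.int64)
    stock_week = np.array([s.week for s in obs.stocks], dtype=np.int64)
    stock_val = np.array([s.value for s in obs.stocks], dtype=float)
    stock_sig = np.array([s.sigma for s in obs.stocks], dtype=float)
    return (
        obs.nee.astype(float), obs.nee_sigma.astype(float),
        (obs.nee_present & use),
        obs.reco.astype(float), obs.reco_sigma.astype(float),
        (obs.reco_present & use),
        obs.lai.astype(float), obs.lai_sigma.astype(float),
        (obs.lai_present & use),
        stock_pool, stock_week, stock_val, stock_sig,
    )


def log_likelihood(result: dalec.SimulationResult, obs: ObservationSet,
                   normalisation: float = SQRT_NORMALISATION) -> float:
    """Normalised Gaussian log-likelihood of a trajectory given observations.

    Per stream the misfit is ``-0.5 * sum(((model - obs) / sigma)^2)`` over
    assimilated, present points (model Reco = Ra + Rh, model NEE =
    Reco - GPP, model LAI = c_fol / LMA); each stream is multiplied by
    ``normalisation`` (0.5 implements the square-root rule).
    """
    if result.n_weeks != obs.n_weeks:
        raise ValueError(
            f"trajectory ({result.n_weeks} weeks) misaligned with "
            f"observations ({obs.n_weeks} weeks)")
    arrays = _obs_arrays(obs)
    n_points = int(arrays[2].sum() + arrays[5].sum() + arrays[8].sum()
                   + len(obs.stocks))
    if n_points == 0:
        warnings.warn("no present observations; log-likelihood is 0",
                      stacklevel=2)
        return 0.0
    return float(_kernel.log_likelihood_kernel(
        result.fluxes, result.lai, result.pools, *arrays,
        float(normalisation)))


def log_prior(params, priors: PriorSpec) -> float:
    """Log prior density (up to a constant) of a parameter vector.

    Uniform quantities contribute 0 inside their bounds; log-uniform
    quantities contribute ``-log(value)``; anything outside its bounds, or
    an allocation-fraction triple summing above 1, gives -inf.
    """
    x = params.as_vector() if hasattr(params, "as_vector") else np.asarray(params, float)
    if len(x) != len(priors):
        raise ValueError(
            f"parameter vector has {len(x)} entries but priors cover "
            f"{len(priors)} quantities")
    if (x < priors.lows).any() or (x > priors.highs).any():
        return -np.inf
    if {"f_fol", "f_lab", "f_root"} <= set(priors.names):
        idx = [priors.names.index(n) for n in ("f_fol", "f_lab", "f_root")]
        if x[idx].sum() > 1.0:
            return -np.inf
    return float(-(np.log(x[priors.log_scale])).sum())


def propose(current: np.ndarray, covariance: np.ndarray, scale: float,
            rng: np.random.Generator) -> np.ndarray:
    """Multivariate-normal jump from ``current``.

    A non-positive-definite covariance falls back to its diagonal (with a
    warning) so the sampler can always move.
    """
    current = np.asarray(current, float)
    if scale == 0:
        return current.copy()
    try:
        chol = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError:
        warnings.warn("proposal covariance not positive definite; "
                      "falling back to diagonal jitter", stacklevel=2)
        chol = np.diag(np.sqrt(np.clip(np.diag(covariance), 1e-12, None)))
    z = rng.standard_normal(len(current))
    return current + scale * (chol @ z)


@dataclass
class McmcConfig:
    """Sampler settings.

    The reference analysis runs 1e8 proposals per chain; the desk default
    of 1e5 keeps the identical algorithm tractable on one core and is fully
    configurable.
    """

    n_chains: int = 3
    n_proposals: int = 100_000
    burn_in: float = 0.5
    adapt_interval: int = 1000
    proposal_scale: float | None = None   # default 2.38 / sqrt(d)
    subsamples_per_chain: int = 100
    seed: int = 0
    accept_target: float = 0.234
    start_candidates: int = 200
    max_start_tries: int = 200_000

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn-in fraction must lie in [0, 1)")


@dataclass
class McmcChains:
    """Post-burn-in states and diagnostics from every chain."""

    states: list                 # per chain: (n_kept, d) natural-space array
    log_posteriors: list         # per chain: (n_kept,)
    acceptance_rates: list
    names: tuple
    rhat: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return len(self.states)


@dataclass
class PosteriorEnsemble:
    """Pooled posterior parameter vectors (default 3 chains x 100 draws)."""

    parameters: np.ndarray       # (n_members, d)
    chain_ids: np.ndarray
    log_posteriors: np.ndarray
    names: tuple

    def __len__(self):
        return len(self.parameters)

    def column(self, name: str) -> np.ndarray:
        return self.parameters[:, self.names.index(name)]

    def interval(self, name: str, prob: float = 0.95) -> tuple:
        a = (1 - prob) / 2
        col = self.column(name)
        return (float(np.quantile(col, a)), float(np.quantile(col, 1 - a)))

    def median(self, name: str) -> float:
        return float(np.median(self.column(name)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.parameters, columns=list(self.names))
        df.insert(0, "chain", self.chain_ids)
        df.insert(1, "log_posterior", self.log_posteriors)
        return df

    def member_params(self, i: int) -> dalec.ProcessParameters:
        return dalec.ProcessParameters.from_vector(self.parameters[i])


def _split_rhat(chains_cols: np.ndarray) -> float:
    """Split potential-scale-reduction factor for one parameter."""
    halves = []
    for col in chains_cols:
        m = len(col) // 2
        halves.extend([col[:m], col[m:2 * m]])
    halves = np.asarray(halves)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return np.inf if b > 0 else 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _make_logpost(obs, drivers, priors, edc, normalisation, constants,
                  log_likelihood_fn):
    """Build the unit-space posterior closure used by each chain."""
    d = len(priors)
    log_low = np.log(np.where(priors.log_scale, priors.lows, 1.0))
    log_high = np.log(np.where(priors.log_scale, priors.highs, 1.0))
    has_alloc = {"f_fol", "f_lab", "f_root"} <= set(priors.names)
    if has_alloc:
        alloc_idx = np.array([priors.names.index(n)
                              for n in ("f_fol", "f_lab", "f_root")])

    if log_likelihood_fn is not None:
        def logpost(u):
            if (u < 0).any() or (u > 1).any():
                return -np.inf
            x = priors.from_unit(u)
            if has_alloc and x[alloc_idx].sum() > 1.0:
                return -np.inf
            return float(log_likelihood_fn(x))

        return logpost

    if obs is None or drivers is None:
        raise ValueError("run_mcmc needs observations and drivers "
                         "(or a log_likelihood_fn stub)")
    mat, _ = dalec.drivers_to_matrix(drivers)
    ac = constants.as_array()
    arrays = _obs_arrays(obs)

    def logpost(u):
        if (u < 0).any() or (u > 1).any():
            return -np.inf
        x = priors.from_unit(u)
        if has_alloc and x[alloc_idx].sum() > 1.0:
            return -np.inf
        return float(_kernel.forward_logpost_kernel(
            x, mat, ac, *arrays, float(normalisation),
            edc.growth_bound, edc.f_auto_range[0], edc.f_auto_range[1],
            0.0))

    return logpost


def _run_single_chain(logpost, d, config, rng):
    scale = (config.proposal_scale if config.proposal_scale is not None
             else 2.38 / np.sqrt(d))
    # start from the best of a pool of feasible prior draws: a cheap global
    # search that spares the local sampler most of the burn-in transient
    u, lp0 = None, -np.inf
    found = 0
    for _ in range(config.max_start_tries):
        cand = rng.uniform(0.0, 1.0, size=d)
        lp = logpost(cand)
        if np.isfinite(lp):
            found += 1
            if lp > lp0:
                u, lp0 = cand, lp
            if found >= config.start_candidates:
                break
    if u is None:
        raise RuntimeError(
            "no feasible starting point found; revise priors or constraints")

    n = config.n_proposals
    us = np.empty((n, d))
    lps = np.empty(n)
    chol = np.eye(d) * 0.05          # modest initial jumps on the unit cube
    accepted = 0
    window_accepted = 0
    for i in range(n):
        z = rng.standard_normal(d)
        cand = u + scale * (chol @ z)
        lpc = logpost(cand)
        if lpc - lp > np.log(rng.uniform()):
            u, lp = cand, lpc
            accepted += 1
            window_accepted += 1
        us[i] = u
        lps[i] = lp
        if (i + 1) % config.adapt_interval == 0:
            hist = us[(i + 1) // 2:i + 1]
            if len(hist) > 2 * d:
                cov = np.cov(hist.T) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    chol = np.diag(np.sqrt(np.clip(np.diag(cov), 1e-12, None)))
            rate = window_accepted / config.adapt_interval
            scale *= float(np.exp(rate - config.accept_target))
            scale = float(np.clip(scale, 1e-4, 10.0))
            window_accepted = 0

    keep = slice(int(np.floor(config.burn_in * n)), n)
    return us[keep], lps[keep], accepted / n


def run_mcmc(obs: ObservationSet | None, drivers: pd.DataFrame | None,
             priors: PriorSpec | None = None,
             config: McmcConfig | None = None,
             edc: EdcConfig | None = None,
             normalisation: float = SQRT_NORMALISATION,
             constants: acm.AcmConstants | None = None,
             log_likelihood_fn=None) -> McmcChains:
    """Sample the posterior with adaptive-proposal Metropolis chains.

    Proposals violating the EDCs receive -inf posterior density and are
    rejected.  Sampling happens on the prior's unit hypercube, where the
    uniform and log-uniform priors are both flat; per-chain seeds derive
    from the master seed.  ``log_likelihood_fn`` (mapping a natural-space
    parameter vector to a log density) replaces the forward-model
    likelihood for toy problems and sampler validation.

    A potential-scale-reduction factor above 1.2 for any quantity triggers
    a warning, not a failure.
    """
    if priors is None:
        priors = PriorSpec.from_registry()
    if config is None:
        config = McmcConfig()
    if edc is None:
        edc = EdcConfig()
    if constants is None:
        constants = acm.load_acm_constants()
    logpost = _make_logpost(obs, drivers, priors, edc, normalisation,
                            constants, log_likelihood_fn)
    d = len(priors)
    states, lps, rates = [], [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        u_kept, lp_kept, rate = _run_single_chain(logpost, d, config, rng)
        states.append(np.vstack([priors.from_unit(u) for u in u_kept]))
        lps.append(lp_kept)
        rates.append(rate)
    if not any(len(s) for s in states):
        raise RuntimeError("no states retained; increase proposals or "
                           "revise the proposal scale")
    rhat = None
    if config.n_chains >= 2:
        rhat = np.array([
            _split_rhat(np.array([s[:, j] for s in states]))
            for j in range(d)
        ])
        if np.nanmax(rhat) > 1.2:
            warnings.warn(
                f"potential scale reduction factor up to {np.nanmax(rhat):.2f} "
                "(> 1.2); chains may not have converged", stacklevel=2)
    return McmcChains(states=states, log_posteriors=lps,
                      acceptance_rates=rates, names=priors.names, rhat=rhat)


def load_config(path):
    """Load priors, EDC bounds and sampler settings from one YAML file.

    Recognised top-level keys (all optional): ``registry`` (the prior /
    parameter table, same schema as the shipped parameters.yaml), ``edc``
    (fields of :class:`EdcConfig`) and ``mcmc`` (fields of
    :class:`McmcConfig`).  Returns ``(priors, edc, mcmc)``.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "registry" in doc:
        registry = dalec.load_registry(path)
        priors = PriorSpec.from_registry(registry)
    else:
        priors = PriorSpec.from_registry()
    edc = EdcConfig(**doc.get("edc", {}))
    if "f_auto_range" in doc.get("edc", {}):
        edc.f_auto_range = tuple(edc.f_auto_range)
    mcmc = McmcConfig(**doc.get("mcmc", {}))
    return priors, edc, mcmc


def extract_ensemble(chains: McmcChains,
                     per_chain: int = 100) -> PosteriorEnsemble:
    """Pool evenly spaced (thinned) draws from every chain."""
    params, ids, lps = [], [], []
    for c, (s, lp) in enumerate(zip(chains.states, chains.log_posteriors)):
        if per_chain > len(s):
            raise ValueError(
                f"requested {per_chain} subsamples but chain {c} holds "
                f"only {len(s)} post-burn-in states")
        if per_chain == 0:
            continue
        idx = np.unique(np.linspace(0, len(s) - 1, per_chain).round()
                        .astype(int))
        # linspace can collide on short chains; pad deterministically
        while len(idx) < per_chain:
            extra = [i for i in range(len(s)) if i not in set(idx)]
            idx = np.sort(np.append(idx, extra[:per_chain - len(idx)]))
        params.append(s[idx])
        ids.append(np.full(per_chain, c))
        lps.append(lp[idx])
    if not params:
        warnings.warn("empty posterior ensemble (per_chain=0)", stacklevel=2)
        d = len(chains.names)
        return PosteriorEnsemble(parameters=np.empty((0, d)),
                                 chain_ids=np.empty(0, int),
                                 log_posteriors=np.empty(0),
                                 names=chains.names)
    return PosteriorEnsemble(parameters=np.vstack(params),
                             chain_ids=np.concatenate(ids),
                             log_posteriors=np.concatenate(lps),
                             names=chains.names)
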