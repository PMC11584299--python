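# Methods

This note documents the model equations, the numerical and statistical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The carbon mass-balance model

Six pools (gC m⁻²): labile, foliage, fine root, wood/structural, litter,
soil organic matter (SOM). The state advances weekly over a 365.25-day
year split into 52 weeks of 7 days, week 52 absorbing the 8.25-day
remainder; day-of-year is evaluated mid-week. Each step, in order:

1. `LAI = C_fol / LMA`; GPP from the canopy submodel (below), scaled by
   the calibrated whole-canopy factor `gpp_scale`.
2. `Ra = f_auto · GPP`; `NPP = GPP − Ra`, split by fixed fractions
   `f_lab`, `f_fol`, `f_root`, with wood receiving the residual
   (the three fractions are constrained to sum ≤ 1 jointly with a prior
   support restriction).
3. Phenology. Leaf flush moves labile carbon to foliage, senescence moves
   foliage to litter. Both use a *wrapped-Gaussian* day-of-year weight
   bell `w(d) ∝ Σ_k exp(−((d − d_c + 365k)/r)²/2)` normalised over the
   365-day year, and a *survival-exponent* release rule: in a week whose
   daily weights sum to `s`, the pool releases the fraction
   `1 − (1 − F)^s`. Survival factors then telescope exactly, so the
   annual released fraction equals the completeness parameter `F` to
   round-off regardless of how the year is discretised. `F` is capped by
   the calibrated `release_cap` (< 1) to avoid the degenerate
   complete-release case. The labile-release window centre is
   `d_onset + onset_lag`, allowing flush to trail the onset signal.
4. Turnover and decomposition. Fine-root mortality feeds litter, wood
   mortality feeds SOM directly (the structural pool includes coarse
   roots, and its mortality enters the peat column below the litter
   layer). Litter splits between mineralisation (`r_lit`, to Rh) and
   humification (`d_lit2som`, to SOM); SOM mineralises at `r_som`. These
   three are scaled by the exponential temperature factor
   `f_T = exp(θ·T_mean)` with `T_mean = (T_min + T_max)/2`; the litter
   fluxes carry their own sensitivity `theta_lit`, the SOM flux uses
   `theta`.
5. Discrete losses. Every pool loss is a fraction
   `min(1, rate · f_T · Δt)` of the start-of-step stock (competing litter
   losses share one joint fraction proportionally), so pools cannot go
   negative by construction; a clamp-to-zero guard remains and sets a
   flag that the calibration's constraint E4 treats as a rejection.
   Because all transfers are internal, the conservation identity
   `Δ(ΣC) = (GPP − Ra − Rh)·Δt` holds to machine precision; the test
   suite verifies `|residual| < 10⁻⁹ · ΣC` for random feasible parameter
   vectors.

The explicit discrete-loss rule (rather than exact exponential decay
within the step) matches the difference-equation convention of this model
family and makes the fixed-point used in the stationarity test solvable in
closed form.

## Canopy photosynthesis (ACM-1)

Daily GPP is computed from LAI, the diurnal temperature range, shortwave
radiation, ambient CO2 and day length. Canopy conductance
`g_c = |ψ_d|^{e10} / (e6·R_tot + 0.5(T_max − T_min))`; photosynthetic
demand `p = LAI · c_eff · e^{e8·T_max} / g_c` (foliar nitrogen is folded
into the calibrated efficiency `c_eff`, removing an unidentifiable
factor); internal CO2 from the quadratic
`c_i = ½(c_a + q − p + √((c_a + q − p)² − 4(c_a·q − p·e3)))` with
`q = e3 − e4`. This is the *larger* root — the physical branch, which
approaches `c_a` (no drawdown) as demand vanishes and the compensation
point `e3` under saturating demand. The light-limited efficiency is
`e0 = e7·LAI²/(LAI² + e9)`, and the co-limited canopy rate
`e0·I·g_c(c_a − c_i) / (e0·I + g_c(c_a − c_i))` is scaled by the
day-length correction `(e2·L + e5)`.

The ten empirical coefficients plus the fixed hydraulics (ψ_d = −2 MPa,
R_tot = 1) ship as versioned, checksummed YAML (`data/acm1.yaml`); they
are data, not code, so another calibrated vintage can be substituted
without touching the source. GPP is monotone non-decreasing in CO2, LAI
and radiation over the physical range — the property tests assert this —
which is the mechanism that lets rising CO2 force a productivity trend.

## The 28 calibrated quantities

The registry (`data/parameters.yaml`) fixes the vector layout: 18 core
process parameters (allocation fractions, phenology dates/widths/
completeness, turnover and decomposition rates, temperature
sensitivities, canopy efficiency, LMA), 4 auxiliaries (`theta_lit`,
`gpp_scale`, `release_cap`, `onset_lag`), and the 6 initial pools. The
auxiliary identities are this package's documented choice — the original
table is configuration-driven here precisely so the identities can be
swapped without code change. Priors are independent uniforms, log-uniform
for rate-like and stock-like quantities whose ranges span orders of
magnitude; the shipped ranges are deliberately broad (e.g. `r_som` over
10⁻⁸–10⁻³ d⁻¹, initial SOM over 5–200 kgC m⁻²) and documented per entry
in the YAML.

## Likelihood, constraints, sampler

**Likelihood.** Per stream (NEE, Reco, LAI, stocks), the Gaussian
log-misfit `−½ Σ ((model − obs)/σ)²` over assimilated, present points;
each stream is multiplied by the square-root normalisation factor 0.5
(the likelihood to the power ½), tempering the hundreds of flux points
against the three stock observations. Applying the factor per stream or
to the total is identical when uniform; per stream is implemented.
Model operators: NEE = Ra + Rh − GPP, Reco = Ra + Rh, LAI = C_fol/LMA;
SOC and fine-root stocks constrain the week-0 pools, the aboveground
stock is compared to C_fol + C_wood at week 0 (the mapping is
configurable, since "aboveground" on a structural pool that includes
coarse roots is ambiguous).

**Constraints (EDCs).** E1 `r_som < r_lit`; E2 `t_root > t_wood`; E3
quasi-steady state, `|log(C_end/C_start)| ≤ log 10` per pool over the
run; E4 no negative-pool clamping; E5 `f_auto ∈ (0.2, 0.8)`. Violating
parameter sets receive −∞ posterior density. The set is a registry with
per-rule switches and bounds; `check_edcs` reports *all* violated rules,
not just the first.

**Sampler.** Adaptive-proposal Metropolis on the priors' unit hypercube,
where both uniform and log-uniform priors are flat (the Jacobian of the
log transform exactly absorbs the 1/x density). Per chain: the start
point is the best of 200 feasible prior draws — a cheap global search
that removes most of the burn-in transient in the 28-dimensional space;
proposals are multivariate normal with covariance re-estimated from the
last half of the chain history every 1000 proposals and a global scale
(initial `2.38/√d`) nudged toward the 0.234 acceptance target; burn-in
discards the first half. Three chains with seeds derived from the master
seed run independently; a split potential-scale-reduction factor above
1.2 triggers a warning, not a failure. The posterior ensemble pools 100
evenly spaced post-burn-in draws per chain (300 members). The reference
configuration of this algorithm family uses 10⁸ proposals per chain; the
desk default here is 10⁵, which the twin experiments show is sufficient
under the synthetic conditions for the well-constrained quantities, and
the count is a plain configuration field.

The forward model and likelihood are numba-compiled (one posterior
evaluation ≈ 70 µs on one core), which is what makes 3 × 10⁵-proposal
calibrations a tens-of-seconds operation and the repeated-seed recovery
test tractable.

## Attribution experiments

`fixed_co2_drivers` pins the CO2 column (default: the record's first-week
value; 400.584 ppm for the reference site) and touches nothing else.
`fixed_climate_drivers` replaces every non-CO2 driver at (year, week) by
that week's mean across the years present, removing interannual
meteorological variability while the CO2 trend survives. Both transforms
are idempotent and column-isolated (tested byte-for-byte). Experiments
re-simulate the calibrated ensemble member-by-member under the
transformed drivers; they do not re-run the MCMC (re-calibration under
counterfactual forcing would answer a different question, and the
option remains open by simply calibrating on transformed drivers).

The CO2 effect on GPP is decomposed per member and week: the *direct*
effect is the canopy model evaluated at the factual LAI under factual
versus counterfactual drivers; the *indirect* (LAI-mediated) effect is
the remainder of the full re-simulation difference, so the two parts sum
to the total identically.

## The synthetic site

`generate_drivers` emulates the statistical structure of the seven-year
weekly record: sinusoidal seasonal temperature (amplitude 17 °C, peak
day 200, weekly white noise σ = 2 °C) around a mean annual −0.95 °C; a
9 °C diurnal range; seasonal shortwave radiation (0.5–20.5 MJ m⁻² d⁻¹);
log-normal weekly precipitation (median ≈ 5 mm wk⁻¹); day length from
solar geometry at 64.82 °N; and a CO2 series fixed at 400.584 ppm in the
first week with a winter-high seasonal cycle (amplitude 8 ppm) and a
linear trend of 11.25 ppm yr⁻¹ chosen so the multi-year mean is ≈432 ppm
— both endpoints are site-level statistics of the tower record the
generator mirrors, not global background values. The CO2 series carries
no noise by default so the first-week value is exact.

Observation sampling adds independent Gaussian noise at NEE σ = 0.58 and
Reco σ = 1.0 gC m⁻² d⁻¹; LAI σ is 20% of the value floored at
0.5 m² m⁻², with points present only in ISO weeks 14–39
(April–September); stocks are noisy versions of the initial pools at the
inventory σ values; the default assimilation mask selects 2014, 2016,
2018 and 2020, leaving the other years for validation.

The default truth parameter vector (the registry `default` column) was
chosen once to produce site-magnitude behaviour — annual GPP of a few
hundred gC m⁻² with CUE ≈ 0.52, peak LAI ≈ 2.2, near-steady pools on a
64 kgC m⁻² peat column, allocation 50/30/20 to foliage (direct + labile)
/ wood / fine root, and root/wood residence times of 4–5 years — and to
satisfy every EDC. It is documented, not fitted to any observation.

What the generator does **not** emulate: autocorrelated weather (noise is
white; an AR(1) hook would be the natural extension), extreme events and
the flooding dynamics of a real fen, snow and permafrost, gap structure
in the flux record beyond the LAI seasonal window, or the retrieval
algorithm behind the satellite LAI product. Passing twin experiments
therefore demonstrate that the inference machinery recovers known
parameters under the *stated* noise model, not that the model structure
is adequate for every feature of real tower data.

## Reporting conventions

Quantiles are 0.025 / 0.5 / 0.975 with the type-7 (linear interpolation)
estimator throughout, so interval values are bit-reproducible. Annual
aggregation sums fluxes (gC m⁻² yr⁻¹) and averages states (stocks, LAI),
matching the units in which such budgets are printed. Carbon-use
efficiency and allocation fractions are computed per ensemble member and
then summarised (ratio of member values, not ratio of medians); the
budget table exposes both routes implicitly since it also reports median
NPP and GPP. Residence times are mean stock over mean annual outflux per
member; a zero outflux reports as missing, never infinity. Allocation to
foliage counts the direct share plus the labile share (which is released
to foliage), so the three reported fractions partition NPP exactly.

File round-trips: drivers and observations as tidy CSV; drivers,
trajectories and ensembles also as NetCDF (classic format via the scipy
backend, so no extra binary dependencies).

## Problem sizes

The shipped defaults are desk-scale: 7 × 52 weekly steps, 3 chains ×
10⁵ proposals, 300-member ensembles, 10-seed recovery repeats. The full
test suite runs in about five minutes on one core; the acceptance script
in under a minute per calibration. All sizes are configuration, not
constants.

## Known limitations

* No soil moisture, water-table, snow or methane representation — the
  model deliberately has no moisture input, so wet-year/dry-year
  contrasts are invisible to it.
* No disturbance fluxes; NBE ≡ NEE.
* The auxiliary-parameter identities and EDC list are this package's
  documented choices behind a config-driven registry.
* `gpp_scale` overlaps with `c_eff` in effect (linear scaling versus
  nonlinear drawdown); the pair is weakly identified by design, which
  widens — never narrows — the posterior on either.
* The adaptive sampler targets a unimodal, moderately correlated
  posterior; strongly multimodal landscapes would need tempering or many
  more restarts than the three-chain default.
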