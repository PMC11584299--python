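"""Jit-compiled numerical core: forward model, likelihood, constraint checks.

Everything here operates on flat float64 arrays so the Metropolis sampler can
evaluate ~10^4 proposals per second on one core.  The public, documented
surface lives in :mod:`fenfusion.dalec`, :mod:`fenfusion.acm` and
:mod:`fenfusion.calibration`; those modules delegate to these functions.

Parameter-vector layout (28 entries) follows ``data/parameters.yaml``::

    0  f_auto      7  d_fall      14 r_som      21 onset_lag
    1  f_fol       8  r_fall      15 theta      22 c_lab0
    2  f_lab       9  big_f_fall  16 theta_lit  23 c_fol0
    3  f_root     10  t_root      17 c_eff      24 c_root0
    4  d_onset    11  t_wood      18 lma        25 c_wood0
    5  r_onset    12  r_lit       19 gpp_scale  26 c_lit0
    6  big_f_onset 13 d_lit2som   20 release_cap 27 c_som0

Driver matrix columns: doy, tmin, tmax, swrad, co2, daylength, dt.
Flux matrix columns follow FLUX_NAMES in :mod:`fenfusion.dalec`.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# driver columns
D_DOY, D_TMIN, D_TMAX, D_SWRAD, D_CO2, D_DAYL, D_DT = 0, 1, 2, 3, 4, 5, 6

# flux columns
(
    F_GPP, F_RA, F_NPP,
    F_ALLOC_LAB, F_ALLOC_FOL, F_ALLOC_ROOT, F_ALLOC_WOOD,
    F_LABILE_RELEASE, F_LEAF_FALL, F_ROOT_MORT, F_WOOD_MORT,
    F_DEC_LIT2SOM, F_RH_LIT, F_RH_SOM, F_RH, F_RECO, F_NEE, F_NBE,
) = range(18)

N_FLUXES = 18
N_POOLS = 6
N_PARAMS = 28

DAYS_PER_YEAR = 365
WEEKS_PER_YEAR = 52


@njit(cache=True)
def acm_gpp_scalar(lai, tmin, tmax, swrad, co2, dayl, ceff, ac):
    """ACM-1 daily GPP (gC m-2 d-1). ``ac`` = [e1..e10, psi_d, r_tot]."""
    if lai <= 0.0 or swrad <= 0.0:
        return 0.0
    e2, e3, e4, e5 = ac[1], ac[2], ac[3], ac[4]
    e6, e7, e8, e9, e10 = ac[5], ac[6], ac[7], ac[8], ac[9]
    psi_d, r_tot = ac[10], ac[11]
    trange = 0.5 * (tmax - tmin)
    gc = abs(psi_d) ** e10 / (e6 * r_tot + trange)
    pp = lai * ceff * np.exp(e8 * tmax) / gc
    qq = e3 - e4
    b = co2 + qq - pp
    disc = b * b - 4.0 * (co2 * qq - pp * e3)
    if disc < 0.0:
        return np.nan
    ci = 0.5 * (b + np.sqrt(disc))
    drawdown = co2 - ci
    if drawdown <= 0.0:
        return 0.0
    e0 = e7 * lai * lai / (lai * lai + e9)
    denom = e0 * swrad + gc * drawdown
    if denom <= 0.0:
        return 0.0
    cps = e0 * swrad * gc * drawdown / denom
    gpp = cps * (e2 * dayl + e5)
    return gpp if gpp > 0.0 else 0.0


@njit(cache=True)
def phenology_daily_weights(center, width, n_days):
    """Wrapped-Gaussian daily weights over ``1..n_days``, normalised to 1."""
    w = np.empty(n_days)
    total = 0.0
    for d in range(1, n_days + 1):
        s = 0.0
        for k in (-1, 0, 1):
            z = (d - center + k * n_days) / width
            s += np.exp(-0.5 * z * z)
        w[d - 1] = s
        total += s
    for i in range(n_days):
        w[i] /= total
    return w


@njit(cache=True)
def weekly_weight_sums(center, width):
    """Sum the daily phenology weights over each of the 52 model weeks.

    Weeks 1..51 cover 7 days each; week 52 absorbs the remaining 8 days
    (days 358-365), so the 52 sums add to exactly 1.
    """
    daily = phenology_daily_weights(center, width, DAYS_PER_YEAR)
    out = np.zeros(WEEKS_PER_YEAR)
    for w in range(WEEKS_PER_YEAR - 1):
        s = 0.0
        for d in range(7 * w, 7 * w + 7):
            s += daily[d]
        out[w] = s
    s = 0.0
    for d in range(357, DAYS_PER_YEAR):
        s += daily[d]
    out[WEEKS_PER_YEAR - 1] = s
    return out


@njit(cache=True)
def simulate_kernel(x, drivers, ac):
    """Run the six-pool model over the full driver record.

    Returns ``(pools, fluxes, lai, clamped)`` where ``pools`` has one more
    row than the driver record (initial state first) and ``clamped`` flags
    any step where a pool had to be clipped at zero.
    """
    n = drivers.shape[0]
    pools = np.empty((n + 1, N_POOLS))
    fluxes = np.empty((n, N_FLUXES))
    lai_out = np.empty(n)
    clamped = False

    c_lab, c_fol = x[22], x[23]
    c_root, c_wood = x[24], x[25]
    c_lit, c_som = x[26], x[27]
    pools[0, 0], pools[0, 1], pools[0, 2] = c_lab, c_fol, c_root
    pools[0, 3], pools[0, 4], pools[0, 5] = c_wood, c_lit, c_som

    cap = x[20]
    f_on = min(x[6], cap)
    f_fall = min(x[9], cap)
    onset_center = x[4] + x[21]
    if onset_center > DAYS_PER_YEAR:
        onset_center -= DAYS_PER_YEAR
    onset_w = weekly_weight_sums(onset_center, x[5])
    fall_w = weekly_weight_sums(x[7], x[8])

    f_auto, f_fol_a, f_lab_a, f_root_a = x[0], x[1], x[2], x[3]
    f_wood_a = 1.0 - f_fol_a - f_lab_a - f_root_a
    t_root, t_wood = x[10], x[11]
    r_lit, d_l2s, r_som = x[12], x[13], x[14]
    theta, theta_lit = x[15], x[16]
    ceff, lma, gscale = x[17], x[18], x[19]

    for t in range(n):
        doy = drivers[t, D_DOY]
        tmin = drivers[t, D_TMIN]
        tmax = drivers[t, D_TMAX]
        swrad = drivers[t, D_SWRAD]
        co2 = drivers[t, D_CO2]
        dayl = drivers[t, D_DAYL]
        dt = drivers[t, D_DT]
        tmean = 0.5 * (tmin + tmax)
        week = t % WEEKS_PER_YEAR

        lai = c_fol / lma
        lai_out[t] = lai
        gpp = gscale * acm_gpp_scalar(lai, tmin, tmax, swrad, co2, dayl, ceff, ac)
        ra = f_auto * gpp
        npp = gpp - ra
        al_lab = f_lab_a * npp
        al_fol = f_fol_a * npp
        al_root = f_root_a * npp
        al_wood = f_wood_a * npp

        rel_on = 1.0 - (1.0 - f_on) ** onset_w[week]
        rel_fall = 1.0 - (1.0 - f_fall) ** fall_w[week]
        lab_release = rel_on * c_lab
        leaf_fall = rel_fall * c_fol

        ft = np.exp(theta * tmean)
        ft_lit = np.exp(theta_lit * tmean)
        root_mort = min(1.0, t_root * dt) * c_root
        wood_mort = min(1.0, t_wood * dt) * c_wood
        lit_frac = min(1.0, (r_lit + d_l2s) * ft_lit * dt)
        lit_loss = lit_frac * c_lit
        rh_lit = lit_loss * r_lit / (r_lit + d_l2s) if r_lit + d_l2s > 0 else 0.0
        lit2som = lit_loss - rh_lit
        rh_som = min(1.0, r_som * ft * dt) * c_som

        c_lab = c_lab - lab_release + al_lab * dt
        c_fol = c_fol - leaf_fall + al_fol * dt + lab_release
        c_root = c_root - root_mort + al_root * dt
        c_wood = c_wood - wood_mort + al_wood * dt
        c_lit = c_lit - lit_loss + leaf_fall + root_mort
        c_som = c_som - rh_som + lit2som + wood_mort

        if c_lab < 0.0 or c_fol < 0.0 or c_root < 0.0 or c_wood < 0.0 \
                or c_lit < 0.0 or c_som < 0.0:
            clamped = True
            c_lab = max(c_lab, 0.0)
            c_fol = max(c_fol, 0.0)
            c_root = max(c_root, 0.0)
            c_wood = max(c_wood, 0.0)
            c_lit = max(c_lit, 0.0)
            c_som = max(c_som, 0.0)

        pools[t + 1, 0], pools[t + 1, 1] = c_lab, c_fol
        pools[t + 1, 2], pools[t + 1, 3] = c_root, c_wood
        pools[t + 1, 4], pools[t + 1, 5] = c_lit, c_som

        rh = (rh_lit + rh_som) / dt
        fluxes[t, F_GPP] = gpp
        fluxes[t, F_RA] = ra
        fluxes[t, F_NPP] = npp
        fluxes[t, F_ALLOC_LAB] = al_lab
        fluxes[t, F_ALLOC_FOL] = al_fol
        fluxes[t, F_ALLOC_ROOT] = al_root
        fluxes[t, F_ALLOC_WOOD] = al_wood
        fluxes[t, F_LABILE_RELEASE] = lab_release / dt
        fluxes[t, F_LEAF_FALL] = leaf_fall / dt
        fluxes[t, F_ROOT_MORT] = root_mort / dt
        fluxes[t, F_WOOD_MORT] = wood_mort / dt
        fluxes[t, F_DEC_LIT2SOM] = lit2som / dt
        fluxes[t, F_RH_LIT] = rh_lit / dt
        fluxes[t, F_RH_SOM] = rh_som / dt
        fluxes[t, F_RH] = rh
        fluxes[t, F_RECO] = ra + rh
        fluxes[t, F_NEE] = ra + rh - gpp
        fluxes[t, F_NBE] = ra + rh - gpp

    return pools, fluxes, lai_out, clamped


# EDC bit positions (bit i set => constraint Ei+1 violated)
EDC_BITS = 5


@njit(cache=True)
def check_edcs_kernel(x, pools, clamped, growth_bound, f_auto_lo, f_auto_hi):
    """Return a bitmask of violated ecological/dynamical constraints."""
    mask = 0
    if not (x[14] < x[12]):            # E1: SOM slower than litter
        mask |= 1
    if not (x[10] > x[11]):            # E2: roots faster than wood
        mask |= 2
    n = pools.shape[0] - 1
    logb = np.log(growth_bound)
    for p in range(N_POOLS):           # E3: quasi-steady pools
        c0 = pools[0, p]
        c1 = pools[n, p]
        if c0 <= 0.0 or c1 <= 0.0:
            mask |= 4
            break
        if abs(np.log(c1 / c0)) > logb:
            mask |= 4
            break
    if clamped:                        # E4: no negative-pool clamping
        mask |= 8
    if not (f_auto_lo < x[0] < f_auto_hi):  # E5: plausible CUE
        mask |= 16
    return mask


@njit(cache=True)
def log_likelihood_kernel(
    fluxes, lai, pools,
    nee_val, nee_sig, nee_use,
    reco_val, reco_sig, reco_use,
    lai_val, lai_sig, lai_use,
    stock_pool, stock_week, stock_val, stock_sig,
    normalisation,
):
    """Gaussian misfit per stream, each scaled by ``normalisation``.

    The aboveground-stock observation (stock_pool = -1) is compared to
    c_fol + c_wood at the given week; other stock rows name a pool index.
    """
    n = fluxes.shape[0]
    ll_nee = 0.0
    ll_reco = 0.0
    ll_lai = 0.0
    for t in range(n):
        if nee_use[t]:
            r = (fluxes[t, F_NEE] - nee_val[t]) / nee_sig[t]
            ll_nee += r * r
        if reco_use[t]:
            r = (fluxes[t, F_RECO] - reco_val[t]) / reco_sig[t]
            ll_reco += r * r
        if lai_use[t]:
            r = (lai[t] - lai_val[t]) / lai_sig[t]
            ll_lai += r * r
    total = -0.5 * normalisation * (ll_nee + ll_reco + ll_lai)
    ll_stock = 0.0
    for i in range(stock_pool.shape[0]):
        w = stock_week[i]
        p = stock_pool[i]
        if p == -1:
            model = pools[w, 1] + pools[w, 3]
        else:
            model = pools[w, p]
        r = (model - stock_val[i]) / stock_sig[i]
        ll_stock += r * r
    total += -0.5 * normalisation * ll_stock
    return total


@njit(cache=True)
def forward_logpost_kernel(
    x, drivers, ac,
    nee_val, nee_sig, nee_use,
    reco_val, reco_sig, reco_use,
    lai_val, lai_sig, lai_use,
    stock_pool, stock_week, stock_val, stock_sig,
    normalisation, growth_bound, f_auto_lo, f_auto_hi,
    log_jac,
):
    """One-shot posterior evaluation used inside the sampler.

    ``log_jac`` carries the prior/Jacobian contribution computed by the
    caller in sampling space; EDC violations return -inf.
    """
    pools, fluxes, lai, clamped = simulate_kernel(x, drivers, ac)
    mask = check_edcs_kernel(x, pools, clamped, growth_bound, f_auto_lo, f_auto_hi)
    if mask != 0:
        return -np.inf
    ll = log_likelihood_kernel(
        fluxes, lai, pools,
        nee_val, nee_sig, nee_use,
        reco_val, reco_sig, reco_use,
        lai_val, lai_sig, lai_use,
        stock_pool, stock_week, stock_val, stock_sig,
        normalisation,
    )
    if np.isnan(ll):
        return -np.inf
    return ll + log_jac
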