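"""Numba-compiled Metropolis-within-Gibbs engine for the integrated model.

The joint posterior combines the CJS m-array likelihood, Poisson clutch and
mixture nest-fate likelihoods (on sufficient statistics), Poisson count
observations, and the latent state-transition model. Parameters live in one
flat vector per chain:

* ``x[0:21]`` — top-level scalars (intercepts on the natural scale with
  uniform priors, covariate slopes, year-effect SDs, immigrant age mix q);
* six year-random-effect blocks of length T (link scale, N(0, sigma));
* expected total immigrants ``Om[t]`` (uniform prior);
* latent integer states NY, NA, IY, IA stored as floats;
* latent standard-normal imputations for missing covariates.

Updates are single-site random walks with component-local likelihood deltas;
proposal scales adapt in batches during burn-in (target acceptance ~0.44)
and are frozen afterwards to preserve detailed balance.
"""

import math

import numpy as np
from numba import njit

# top-level scalar indices
I_PBY, I_PBA, I_SIG_PB = 0, 1, 2
I_CSY, I_CSA, I_SIG_CS = 3, 4, 5
I_PNS, I_BR_PNS, I_BT_PNS, I_SIG_PNS = 6, 7, 8, 9
I_SNY, I_SNA, I_BR_SN, I_BT_SN, I_SIG_SN = 10, 11, 12, 13, 14
I_SJ, I_BR_SJ, I_SIG_SJ = 15, 16, 17
I_SA, I_SIG_SA = 18, 19
I_Q = 20
N_SCALAR = 21

TOP_NAMES = (
    "pB_Y", "pB_A", "sigma_pB", "CS_Y", "CS_A", "sigma_CS",
    "pNS", "beta_rain_pNS", "beta_temp_pNS", "sigma_pNS",
    "sN_Y", "sN_A", "beta_rain_sN", "beta_temp_sN", "sigma_sN",
    "sJ", "beta_rain_sJ", "sigma_sJ", "sA", "sigma_sA", "q",
)


def n_params(T: int, n_imputed: int) -> int:
    return N_SCALAR + 11 * T + n_imputed


def block_offsets(T: int) -> dict:
    """Offsets of the vector blocks for a study of T years."""
    E = N_SCALAR
    return {
        "eps_pB": E, "eps_CS": E + T, "eps_pNS": E + 2 * T,
        "eps_sN": E + 3 * T, "eps_sJ": E + 4 * T, "eps_sA": E + 5 * T,
        "Om": E + 6 * T, "NY": E + 7 * T, "NA": E + 8 * T,
        "IY": E + 9 * T, "IA": E + 10 * T, "imputed": E + 11 * T,
    }


@njit(cache=True)
def _invlogit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _logit(p):
    return math.log(p) - math.log(1.0 - p)


# log k! for integer k, tabulated once; counts in these models stay far
# below the table size, with an exact lgamma fallback beyond it
_LOG_FACT = np.concatenate(
    ([0.0], np.cumsum(np.log(np.arange(1.0, 65536.0)))))


@njit(cache=True)
def _lfact(k):
    ki = int(k)
    if 0 <= ki < 65536 and k == ki:
        return _LOG_FACT[ki]
    return math.lgamma(k + 1.0)


@njit(cache=True)
def _pois(k, mu):
    if mu <= 0.0:
        return 0.0 if k <= 0.0 else -np.inf
    return k * math.log(mu) - mu - _lfact(k)


@njit(cache=True)
def _binom(k, n, p):
    if k < 0.0 or k > n:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0.0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n else -np.inf
    return (_lfact(n) - _lfact(k) - _lfact(n - k)
            + k * math.log(p) + (n - k) * math.log(1.0 - p))


@njit(cache=True)
def _refresh_pB(x, t0, t1, pcap, pBY, pBA, PY, PA):
    T = PY.shape[0]
    E = N_SCALAR
    lpBY = _logit(x[I_PBY])
    lpBA = _logit(x[I_PBA])
    for t in range(t0, t1):
        pBY[t] = _invlogit(lpBY + x[E + t])
        pBA[t] = _invlogit(lpBA + x[E + t])
        PY[t] = pBY[t] * pcap[t]
        PA[t] = pBA[t] * pcap[t]


@njit(cache=True)
def _refresh_CS(x, t0, t1, CSY, CSA):
    T = CSY.shape[0]
    E = N_SCALAR
    lCSY = math.log(x[I_CSY])
    lCSA = math.log(x[I_CSA])
    for t in range(t0, t1):
        CSY[t] = math.exp(lCSY + x[E + T + t])
        CSA[t] = math.exp(lCSA + x[E + T + t])


@njit(cache=True)
def _refresh_pNS(x, t0, t1, rainh, temph, PNS):
    T = PNS.shape[0]
    E = N_SCALAR
    lpNS = _logit(x[I_PNS])
    for t in range(t0, t1):
        PNS[t] = _invlogit(lpNS + x[I_BR_PNS] * rainh[t]
                           + x[I_BT_PNS] * temph[t] + x[E + 2 * T + t])


@njit(cache=True)
def _refresh_sN(x, t0, t1, rainh, temph, SNY, SNA):
    T = SNY.shape[0]
    E = N_SCALAR
    lsNY = _logit(x[I_SNY])
    lsNA = _logit(x[I_SNA])
    for t in range(t0, t1):
        SNY[t] = _invlogit(lsNY + x[I_BR_SN] * rainh[t]
                           + x[I_BT_SN] * temph[t] + x[E + 3 * T + t])
        SNA[t] = _invlogit(lsNA + x[I_BR_SN] * rainh[t]
                           + x[I_BT_SN] * temph[t] + x[E + 3 * T + t])


@njit(cache=True)
def _refresh_sJ(x, t0, t1, rainf, SJ):
    T = SJ.shape[0]
    E = N_SCALAR
    lsJ = _logit(x[I_SJ])
    for t in range(t0, t1):
        SJ[t] = _invlogit(lsJ + x[I_BR_SJ] * rainf[t] + x[E + 4 * T + t])


@njit(cache=True)
def _refresh_sA(x, t0, t1, SAr):
    T = SAr.shape[0]
    E = N_SCALAR
    lsA = _logit(x[I_SA])
    for t in range(t0, t1):
        SAr[t] = _invlogit(lsA + x[E + 5 * T + t])


@njit(cache=True)
def _refresh_rates(x, t0, t1, rainh, temph, rainf, pcap,
                   pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr, PY, PA):
    """Recompute every natural-scale rate array for years [t0, t1)."""
    _refresh_pB(x, t0, t1, pcap, pBY, pBA, PY, PA)
    _refresh_CS(x, t0, t1, CSY, CSA)
    _refresh_pNS(x, t0, t1, rainh, temph, PNS)
    _refresh_sN(x, t0, t1, rainh, temph, SNY, SNA)
    _refresh_sJ(x, t0, t1, rainf, SJ)
    _refresh_sA(x, t0, t1, SAr)


@njit(cache=True)
def _refresh_for_scalar(j, x, t0, t1, rainh, temph, rainf, pcap,
                        pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr, PY, PA):
    """Recompute only the rate family a top-level scalar belongs to."""
    if j == I_PBY or j == I_PBA:
        _refresh_pB(x, t0, t1, pcap, pBY, pBA, PY, PA)
    elif j == I_CSY or j == I_CSA:
        _refresh_CS(x, t0, t1, CSY, CSA)
    elif j == I_PNS or j == I_BR_PNS or j == I_BT_PNS:
        _refresh_pNS(x, t0, t1, rainh, temph, PNS)
    elif j == I_SNY or j == I_SNA or j == I_BR_SN or j == I_BT_SN:
        _refresh_sN(x, t0, t1, rainh, temph, SNY, SNA)
    elif j == I_SJ or j == I_BR_SJ:
        _refresh_sJ(x, t0, t1, rainf, SJ)
    elif j == I_SA:
        _refresh_sA(x, t0, t1, SAr)


@njit(cache=True)
def _refresh_for_block(blk, x, t0, t1, rainh, temph, rainf, pcap,
                       pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr, PY, PA):
    """Recompute only the rate family of one year-effect block."""
    if blk == 0:
        _refresh_pB(x, t0, t1, pcap, pBY, pBA, PY, PA)
    elif blk == 1:
        _refresh_CS(x, t0, t1, CSY, CSA)
    elif blk == 2:
        _refresh_pNS(x, t0, t1, rainh, temph, PNS)
    elif blk == 3:
        _refresh_sN(x, t0, t1, rainh, temph, SNY, SNA)
    elif blk == 4:
        _refresh_sJ(x, t0, t1, rainf, SJ)
    else:
        _refresh_sA(x, t0, t1, SAr)


@njit(cache=True)
def _ll_cjs_juv_row(r, act_j, m_j, nv_j, SJ, SAr, PY, PA):
    """Contribution of one juvenile release cohort (cohort r uses sJ[r])."""
    T = PY.shape[0]
    ll = 0.0
    if act_j[r]:
        cum = SJ[r]
        seen = 0.0
        for c in range(r + 1, T):
            p = PY[c] if c == r + 1 else PA[c]
            nu = cum * p
            if m_j[r, c] > 0.0:
                ll += m_j[r, c] * math.log(max(nu, 1e-300))
            seen += nu
            if c < T - 1:
                cum *= (1.0 - p) * SAr[c]
        if nv_j[r] > 0.0:
            ll += nv_j[r] * math.log(max(1.0 - seen, 1e-300))
    return ll


@njit(cache=True)
def _ll_cjs_ad_row(r, act_a, m_a, nv_a, SAr, PA):
    """Contribution of one adult release cohort."""
    T = PA.shape[0]
    ll = 0.0
    if act_a[r]:
        cum = SAr[r]
        seen = 0.0
        for c in range(r + 1, T):
            p = PA[c]
            nu = cum * p
            if m_a[r, c] > 0.0:
                ll += m_a[r, c] * math.log(max(nu, 1e-300))
            seen += nu
            if c < T - 1:
                cum *= (1.0 - p) * SAr[c]
        if nv_a[r] > 0.0:
            ll += nv_a[r] * math.log(max(1.0 - seen, 1e-300))
    return ll


@njit(cache=True)
def _fill_cjs_rowcache(rowc_j, rowc_a, act_j, m_j, nv_j, act_a, m_a, nv_a,
                       SJ, SAr, PY, PA):
    """Per-cohort CJS contributions at the current rates (one full pass)."""
    T = PY.shape[0]
    for r in range(T - 1):
        rowc_j[r] = _ll_cjs_juv_row(r, act_j, m_j, nv_j, SJ, SAr, PY, PA)
        rowc_a[r] = _ll_cjs_ad_row(r, act_a, m_a, nv_a, SAr, PA)


@njit(cache=True)
def _ll_cjs_rows(rmax_j, rmax_a, act_j, m_j, nv_j, act_a, m_a, nv_a,
                 SJ, SAr, PY, PA):
    """CJS log-likelihood restricted to release cohorts r < rmax per age.

    A change in year-t rates touches only cohorts released early enough to
    reach year t, so likelihood deltas can skip the unaffected rows (their
    contributions cancel in the Metropolis ratio).
    """
    T = PY.shape[0]
    ll = 0.0
    for r in range(rmax_j):
        ll += _ll_cjs_juv_row(r, act_j, m_j, nv_j, SJ, SAr, PY, PA)
    for r in range(rmax_a):
        if act_a[r]:
            cum = SAr[r]
            seen = 0.0
            for c in range(r + 1, T):
                p = PA[c]
                nu = cum * p
                if m_a[r, c] > 0.0:
                    ll += m_a[r, c] * math.log(max(nu, 1e-300))
                seen += nu
                if c < T - 1:
                    cum *= (1.0 - p) * SAr[c]
            if nv_a[r] > 0.0:
                ll += nv_a[r] * math.log(max(1.0 - seen, 1e-300))
    return ll


@njit(cache=True)
def _ll_cjs(act_j, m_j, nv_j, act_a, m_a, nv_a, SJ, SAr, PY, PA):
    T = PY.shape[0]
    ll = 0.0
    for r in range(T - 1):
        if act_j[r]:
            cum = SJ[r]
            seen = 0.0
            for c in range(r + 1, T):
                p = PY[c] if c == r + 1 else PA[c]
                nu = cum * p
                if m_j[r, c] > 0.0:
                    ll += m_j[r, c] * math.log(max(nu, 1e-300))
                seen += nu
                if c < T - 1:
                    cum *= (1.0 - p) * SAr[c]
            if nv_j[r] > 0.0:
                ll += nv_j[r] * math.log(max(1.0 - seen, 1e-300))
        if act_a[r]:
            cum = SAr[r]
            seen = 0.0
            for c in range(r + 1, T):
                p = PA[c]
                nu = cum * p
                if m_a[r, c] > 0.0:
                    ll += m_a[r, c] * math.log(max(nu, 1e-300))
                seen += nu
                if c < T - 1:
                    cum *= (1.0 - p) * SAr[c]
            if nv_a[r] > 0.0:
                ll += nv_a[r] * math.log(max(1.0 - seen, 1e-300))
    return ll


@njit(cache=True)
def _ll_clutch_t(t, CSY, CSA, ncl, scl):
    ll = 0.0
    for a in range(2):
        if ncl[a, t] > 0.0:
            cs = CSY[t] if a == 0 else CSA[t]
            if cs <= 0.0:
                return -np.inf
            ll += scl[a, t] * math.log(cs) - ncl[a, t] * cs
    return ll


@njit(cache=True)
def _ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc):
    ll = 0.0
    pns = PNS[t]
    for a in range(2):
        sn = SNY[t] if a == 0 else SNA[t]
        if nsucc[a, t] > 0.0:
            ll += nsucc[a, t] * math.log(max(pns, 1e-300))
            if sumf[a, t] > 0.0:
                ll += sumf[a, t] * math.log(max(sn, 1e-300))
            if sumcf[a, t] > 0.0:
                ll += sumcf[a, t] * math.log(max(1.0 - sn, 1e-300))
        for c in range(failc.shape[2]):
            if failc[a, t, c] > 0.0:
                mix = (1.0 - pns) + pns * (1.0 - sn) ** c
                ll += failc[a, t, c] * math.log(max(mix, 1e-300))
    return ll


@njit(cache=True)
def _ll_counts_t(t, ny, na, pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                 firstcl, eggs, fled):
    ll = 0.0
    by = ny * pBY[t]
    ba = na * pBA[t]
    if not np.isnan(firstcl[t]):
        ll += _pois(firstcl[t], by + ba)
    ey = by * CSY[t]
    ea = ba * CSA[t]
    if not np.isnan(eggs[t]):
        ll += _pois(eggs[t], ey + ea)
    if not np.isnan(fled[t]):
        ll += _pois(fled[t], ey * PNS[t] * SNY[t] + ea * PNS[t] * SNA[t])
    return ll


@njit(cache=True)
def _ll_newr_t(t, OM, pcap, newr):
    if t < 1 or np.isnan(newr[t]):
        return 0.0
    return _pois(newr[t], pcap[t] * OM[t])


@njit(cache=True)
def _ll_trans_t(t, NY, NA, IY, IA, OM, q,
                pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr):
    """Transition into year t (t >= 1) plus the immigrant Poisson terms."""
    tm = t - 1
    r = NY[t] - IY[t]
    s = NA[t] - IA[t]
    ntot = NY[tm] + NA[tm]
    if r < 0.0 or s < 0.0 or s > ntot:
        return -np.inf
    FY = pBY[tm] * CSY[tm] * PNS[tm] * SNY[tm]
    FA = pBA[tm] * CSA[tm] * PNS[tm] * SNA[tm]
    mu = 0.5 * SJ[tm] * (NY[tm] * FY + NA[tm] * FA)
    ll = _pois(r, mu)
    ll += _binom(s, ntot, SAr[tm])
    ll += _pois(IY[t], q * OM[t])
    ll += _pois(IA[t], (1.0 - q) * OM[t])
    return ll


@njit(cache=True)
def _ll_trans_all(NY, NA, IY, IA, OM, q,
                  pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr):
    T = NY.shape[0]
    ll = 0.0
    for t in range(1, T):
        ll += _ll_trans_t(t, NY, NA, IY, IA, OM, q,
                          pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr)
        if ll == -np.inf:
            return ll
    return ll


@njit(cache=True)
def _ll_counts_all(NY, NA, pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                   firstcl, eggs, fled):
    T = NY.shape[0]
    ll = 0.0
    for t in range(T):
        ll += _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                           PNS, SNY, SNA, firstcl, eggs, fled)
    return ll


@njit(cache=True)
def _ll_clutch_all(CSY, CSA, ncl, scl):
    T = CSY.shape[0]
    ll = 0.0
    for t in range(T):
        ll += _ll_clutch_t(t, CSY, CSA, ncl, scl)
    return ll


@njit(cache=True)
def _ll_nest_all(PNS, SNY, SNA, nsucc, sumf, sumcf, failc):
    T = PNS.shape[0]
    ll = 0.0
    for t in range(T):
        ll += _ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
    return ll


@njit(cache=True)
def _ll_imm_all(IY, IA, OM, q):
    T = IY.shape[0]
    ll = 0.0
    for t in range(1, T):
        ll += _pois(IY[t], q * OM[t]) + _pois(IA[t], (1.0 - q) * OM[t])
    return ll


@njit(cache=True)
def _ll_newr_all(OM, pcap, newr):
    T = OM.shape[0]
    ll = 0.0
    for t in range(1, T):
        ll += _ll_newr_t(t, OM, pcap, newr)
    return ll


@njit(cache=True)
def _eps_prior(x, off, T, sigma):
    if sigma <= 0.0:
        return -np.inf
    ss = 0.0
    for t in range(T):
        ss += x[off + t] * x[off + t]
    return -T * math.log(sigma) - 0.5 * ss / (sigma * sigma)


@njit(cache=True)
def full_log_post(x, act_j, m_j, nv_j, act_a, m_a, nv_a,
                  ncl, scl, nsucc, sumf, sumcf, failc,
                  firstcl, eggs, fled, newr, pcap,
                  rainh0, temph0, rainf0, imp_rh, imp_th, imp_rf,
                  lo, hi, om_max, nmax):
    """Joint log posterior (used for initialization checks and tests)."""
    T = pcap.shape[0]
    E = N_SCALAR
    for j in range(N_SCALAR):
        if x[j] <= lo[j] or x[j] >= hi[j]:
            return -np.inf
    off = block_offsets_nb(T)
    OM = x[off[6]:off[6] + T]
    NY = x[off[7]:off[7] + T]
    NA = x[off[8]:off[8] + T]
    IY = x[off[9]:off[9] + T]
    IA = x[off[10]:off[10] + T]
    for t in range(1, T):
        if OM[t] < 0.0 or OM[t] > om_max:
            return -np.inf
    if NY[0] < 0.0 or NY[0] > nmax or NA[0] < 0.0 or NA[0] > nmax:
        return -np.inf

    rainh = rainh0.copy()
    temph = temph0.copy()
    rainf = rainf0.copy()
    k = off[11]
    for i in range(imp_rh.shape[0]):
        rainh[imp_rh[i]] = x[k]
        k += 1
    for i in range(imp_th.shape[0]):
        temph[imp_th[i]] = x[k]
        k += 1
    for i in range(imp_rf.shape[0]):
        rainf[imp_rf[i]] = x[k]
        k += 1

    pBY = np.empty(T); pBA = np.empty(T)
    CSY = np.empty(T); CSA = np.empty(T)
    PNS = np.empty(T); SNY = np.empty(T); SNA = np.empty(T)
    SJ = np.empty(T); SAr = np.empty(T)
    PY = np.empty(T); PA = np.empty(T)
    _refresh_rates(x, 0, T, rainh, temph, rainf, pcap,
                   pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr, PY, PA)

    ll = _ll_cjs(act_j, m_j, nv_j, act_a, m_a, nv_a, SJ, SAr, PY, PA)
    ll += _ll_clutch_all(CSY, CSA, ncl, scl)
    ll += _ll_nest_all(PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
    ll += _ll_counts_all(NY, NA, pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                         firstcl, eggs, fled)
    ll += _ll_newr_all(OM, pcap, newr)
    ll += _ll_trans_all(NY, NA, IY, IA, OM, x[I_Q],
                        pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr)
    ll += _eps_prior(x, off[0], T, x[I_SIG_PB])
    ll += _eps_prior(x, off[1], T, x[I_SIG_CS])
    ll += _eps_prior(x, off[2], T, x[I_SIG_PNS])
    ll += _eps_prior(x, off[3], T, x[I_SIG_SN])
    ll += _eps_prior(x, off[4], T, x[I_SIG_SJ])
    ll += _eps_prior(x, off[5], T, x[I_SIG_SA])
    k = off[11]
    n_imp = imp_rh.shape[0] + imp_th.shape[0] + imp_rf.shape[0]
    for i in range(n_imp):
        ll += -0.5 * x[k + i] * x[k + i]
    return ll


@njit(cache=True)
def block_offsets_nb(T):
    out = np.empty(12, dtype=np.int64)
    for b in range(12):
        out[b] = N_SCALAR + b * T if b < 12 else 0
    return out


@njit(cache=True)
def run_chain(x, scales, n_iter, n_burn, thin, seed,
              act_j, m_j, nv_j, act_a, m_a, nv_a,
              ncl, scl, nsucc, sumf, sumcf, failc,
              firstcl, eggs, fled, newr, pcap,
              rainh, temph, rainf, imp_rh, imp_th, imp_rf,
              lo, hi, om_max, nmax):
    """Run one MCMC chain; returns (draws, acceptance_rates).

    ``x`` is modified in place (current state). ``rainh``/``temph``/``rainf``
    must already contain the imputed values from ``x``; they are kept in sync
    when imputation parameters move. Proposal ``scales`` adapt during burn-in
    only.
    """
    np.random.seed(seed)
    T = pcap.shape[0]
    E = N_SCALAR
    off_eps_pB = E
    off_eps_CS = E + T
    off_eps_pNS = E + 2 * T
    off_eps_sN = E + 3 * T
    off_eps_sJ = E + 4 * T
    off_eps_sA = E + 5 * T
    off_Om = E + 6 * T
    off_NY = E + 7 * T
    off_NA = E + 8 * T
    off_IY = E + 9 * T
    off_IA = E + 10 * T
    off_imp = E + 11 * T
    n_par = off_imp + imp_rh.shape[0] + imp_th.shape[0] + imp_rf.shape[0]

    OM = x[off_Om:off_Om + T]
    NY = x[off_NY:off_NY + T]
    NA = x[off_NA:off_NA + T]
    IY = x[off_IY:off_IY + T]
    IA = x[off_IA:off_IA + T]

    pBY = np.empty(T); pBA = np.empty(T)
    CSY = np.empty(T); CSA = np.empty(T)
    PNS = np.empty(T); SNY = np.empty(T); SNA = np.empty(T)
    SJ = np.empty(T); SAr = np.empty(T)
    PY = np.empty(T); PA = np.empty(T)
    _refresh_rates(x, 0, T, rainh, temph, rainf, pcap,
                   pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ, SAr, PY, PA)

    # per-cohort CJS contributions cached within each year-effect sweep
    nrow = T - 1 if T > 1 else 1
    rowc_j = np.zeros(nrow)
    rowc_a = np.zeros(nrow)
    tmp_j = np.zeros(nrow)
    tmp_a = np.zeros(nrow)

    n_kept = (n_iter - n_burn) // thin
    draws = np.empty((n_kept, n_par))
    acc = np.zeros(n_par)
    tries = np.zeros(n_par)
    acc_b = np.zeros(n_par)
    tries_b = np.zeros(n_par)
    kept = 0

    for it in range(n_iter):
        # ---- top-level scalars ----
        # cache the current component totals once per sweep; accepted
        # proposals overwrite exactly the totals they recompute, so the old
        # side of every Metropolis ratio is a lookup, not a re-evaluation.
        # (q is updated last and only its own immigrant terms, so the stale
        # tot_trans after a q accept is never read within this sweep.)
        tot_cjs_j = _ll_cjs_rows(T - 1, 0, act_j, m_j, nv_j,
                                 act_a, m_a, nv_a, SJ, SAr, PY, PA)
        tot_cjs_a = _ll_cjs_rows(0, T - 1, act_j, m_j, nv_j,
                                 act_a, m_a, nv_a, SJ, SAr, PY, PA)
        tot_clutch = _ll_clutch_all(CSY, CSA, ncl, scl)
        tot_nest = _ll_nest_all(PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
        tot_counts = _ll_counts_all(NY, NA, pBY, pBA, CSY, CSA,
                                    PNS, SNY, SNA, firstcl, eggs, fled)
        tot_trans = _ll_trans_all(NY, NA, IY, IA, OM, x[I_Q],
                                  pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                  SJ, SAr)
        for j in range(N_SCALAR):
            sig_only = (j == I_SIG_PB or j == I_SIG_CS or j == I_SIG_PNS
                        or j == I_SIG_SN or j == I_SIG_SJ or j == I_SIG_SA)
            xo = x[j]
            prop = xo + np.random.normal() * scales[j]
            tries_b[j] += 1.0
            if it >= n_burn:
                tries[j] += 1.0
            if prop <= lo[j] or prop >= hi[j]:
                continue
            if sig_only:
                if j == I_SIG_PB:
                    o = off_eps_pB
                elif j == I_SIG_CS:
                    o = off_eps_CS
                elif j == I_SIG_PNS:
                    o = off_eps_pNS
                elif j == I_SIG_SN:
                    o = off_eps_sN
                elif j == I_SIG_SJ:
                    o = off_eps_sJ
                else:
                    o = off_eps_sA
                llo = _eps_prior(x, o, T, xo)
                lln = _eps_prior(x, o, T, prop)
            elif j == I_Q:
                llo = _ll_imm_all(IY, IA, OM, xo)
                lln = _ll_imm_all(IY, IA, OM, prop)
            else:
                use_cjs = (j == I_PBY or j == I_PBA or j == I_SJ
                           or j == I_BR_SJ or j == I_SA)
                use_clutch = (j == I_CSY or j == I_CSA)
                use_nest = (j == I_PNS or j == I_BR_PNS or j == I_BT_PNS
                            or j == I_SNY or j == I_SNA or j == I_BR_SN
                            or j == I_BT_SN)
                use_counts = (j == I_PBY or j == I_PBA or use_clutch
                              or use_nest)
                # juvenile-survival scalars never touch the adult m-array
                juv_only = (j == I_SJ or j == I_BR_SJ)
                llo = tot_trans
                if use_cjs:
                    llo += tot_cjs_j
                    if not juv_only:
                        llo += tot_cjs_a
                if use_clutch:
                    llo += tot_clutch
                if use_nest:
                    llo += tot_nest
                if use_counts:
                    llo += tot_counts
                x[j] = prop
                _refresh_for_scalar(j, x, 0, T, rainh, temph, rainf, pcap,
                                    pBY, pBA, CSY, CSA, PNS, SNY, SNA, SJ,
                                    SAr, PY, PA)
                new_cjs_j = tot_cjs_j
                new_cjs_a = tot_cjs_a
                new_clutch = tot_clutch
                new_nest = tot_nest
                new_counts = tot_counts
                lln = 0.0
                if use_cjs:
                    new_cjs_j = _ll_cjs_rows(T - 1, 0, act_j, m_j, nv_j,
                                             act_a, m_a, nv_a, SJ, SAr,
                                             PY, PA)
                    lln += new_cjs_j
                    if not juv_only:
                        new_cjs_a = _ll_cjs_rows(0, T - 1, act_j, m_j, nv_j,
                                                 act_a, m_a, nv_a, SJ, SAr,
                                                 PY, PA)
                        lln += new_cjs_a
                if use_clutch:
                    new_clutch = _ll_clutch_all(CSY, CSA, ncl, scl)
                    lln += new_clutch
                if use_nest:
                    new_nest = _ll_nest_all(PNS, SNY, SNA, nsucc, sumf,
                                            sumcf, failc)
                    lln += new_nest
                if use_counts:
                    new_counts = _ll_counts_all(NY, NA, pBY, pBA, CSY, CSA,
                                                PNS, SNY, SNA, firstcl,
                                                eggs, fled)
                    lln += new_counts
                new_trans = _ll_trans_all(NY, NA, IY, IA, OM, x[I_Q],
                                          pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                          SJ, SAr)
                lln += new_trans
                if math.log(np.random.random()) < lln - llo:
                    acc_b[j] += 1.0
                    if it >= n_burn:
                        acc[j] += 1.0
                    tot_cjs_j = new_cjs_j
                    tot_cjs_a = new_cjs_a
                    tot_clutch = new_clutch
                    tot_nest = new_nest
                    tot_counts = new_counts
                    tot_trans = new_trans
                else:
                    x[j] = xo
                    _refresh_for_scalar(j, x, 0, T, rainh, temph, rainf,
                                        pcap, pBY, pBA, CSY, CSA, PNS, SNY,
                                        SNA, SJ, SAr, PY, PA)
                continue
            # sigma / q path (no rate refresh needed)
            if math.log(np.random.random()) < lln - llo:
                x[j] = prop
                acc_b[j] += 1.0
                if it >= n_burn:
                    acc[j] += 1.0

        # ---- year random effects ----
        for blk in range(6):
            if blk == 0:
                o = off_eps_pB; sg = x[I_SIG_PB]
            elif blk == 1:
                o = off_eps_CS; sg = x[I_SIG_CS]
            elif blk == 2:
                o = off_eps_pNS; sg = x[I_SIG_PNS]
            elif blk == 3:
                o = off_eps_sN; sg = x[I_SIG_SN]
            elif blk == 4:
                o = off_eps_sJ; sg = x[I_SIG_SJ]
            else:
                o = off_eps_sA; sg = x[I_SIG_SA]
            if blk == 0 or blk == 4 or blk == 5:
                _fill_cjs_rowcache(rowc_j, rowc_a, act_j, m_j, nv_j,
                                   act_a, m_a, nv_a, SJ, SAr, PY, PA)
            for t in range(T):
                j = o + t
                xo = x[j]
                prop = xo + np.random.normal() * scales[j]
                tries_b[j] += 1.0
                if it >= n_burn:
                    tries[j] += 1.0
                # a change at year t reaches cohorts released before t only;
                # the old side comes from the sweep's row cache
                rma_sa = t + 1 if t + 1 < T - 1 else T - 1
                llo = 0.0
                if blk == 0:
                    for r in range(t):
                        llo += rowc_j[r]
                    for r in range(t):
                        llo += rowc_a[r]
                elif blk == 4:
                    if t < T - 1:
                        llo += rowc_j[t]
                elif blk == 5:
                    for r in range(t):
                        llo += rowc_j[r]
                    for r in range(rma_sa):
                        llo += rowc_a[r]
                if blk == 1:
                    llo += _ll_clutch_t(t, CSY, CSA, ncl, scl)
                if blk == 2 or blk == 3:
                    llo += _ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf,
                                      failc)
                if blk <= 3:
                    llo += _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                        PNS, SNY, SNA, firstcl, eggs, fled)
                if t + 1 < T:
                    llo += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                llo += -0.5 * xo * xo / (sg * sg)
                x[j] = prop
                _refresh_for_block(blk, x, t, t + 1, rainh, temph, rainf,
                                   pcap, pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr, PY, PA)
                lln = 0.0
                if blk == 0:
                    for r in range(t):
                        tmp_j[r] = _ll_cjs_juv_row(r, act_j, m_j, nv_j,
                                                   SJ, SAr, PY, PA)
                        lln += tmp_j[r]
                    for r in range(t):
                        tmp_a[r] = _ll_cjs_ad_row(r, act_a, m_a, nv_a,
                                                  SAr, PA)
                        lln += tmp_a[r]
                elif blk == 4:
                    if t < T - 1:
                        tmp_j[t] = _ll_cjs_juv_row(t, act_j, m_j, nv_j,
                                                   SJ, SAr, PY, PA)
                        lln += tmp_j[t]
                elif blk == 5:
                    for r in range(t):
                        tmp_j[r] = _ll_cjs_juv_row(r, act_j, m_j, nv_j,
                                                   SJ, SAr, PY, PA)
                        lln += tmp_j[r]
                    for r in range(rma_sa):
                        tmp_a[r] = _ll_cjs_ad_row(r, act_a, m_a, nv_a,
                                                  SAr, PA)
                        lln += tmp_a[r]
                if blk == 1:
                    lln += _ll_clutch_t(t, CSY, CSA, ncl, scl)
                if blk == 2 or blk == 3:
                    lln += _ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf,
                                      failc)
                if blk <= 3:
                    lln += _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                        PNS, SNY, SNA, firstcl, eggs, fled)
                if t + 1 < T:
                    lln += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                lln += -0.5 * prop * prop / (sg * sg)
                if math.log(np.random.random()) < lln - llo:
                    acc_b[j] += 1.0
                    if it >= n_burn:
                        acc[j] += 1.0
                    if blk == 0:
                        for r in range(t):
                            rowc_j[r] = tmp_j[r]
                            rowc_a[r] = tmp_a[r]
                    elif blk == 4:
                        if t < T - 1:
                            rowc_j[t] = tmp_j[t]
                    elif blk == 5:
                        for r in range(t):
                            rowc_j[r] = tmp_j[r]
                        for r in range(rma_sa):
                            rowc_a[r] = tmp_a[r]
                else:
                    x[j] = xo
                    _refresh_for_block(blk, x, t, t + 1, rainh, temph,
                                       rainf, pcap, pBY, pBA, CSY, CSA, PNS,
                                       SNY, SNA, SJ, SAr, PY, PA)

        # ---- expected immigrant totals ----
        for t in range(1, T):
            j = off_Om + t
            xo = x[j]
            prop = xo + np.random.normal() * scales[j]
            tries_b[j] += 1.0
            if it >= n_burn:
                tries[j] += 1.0
            if prop < 0.0 or prop > om_max:
                continue
            q = x[I_Q]
            llo = (_ll_newr_t(t, OM, pcap, newr)
                   + _pois(IY[t], q * OM[t]) + _pois(IA[t], (1.0 - q) * OM[t]))
            x[j] = prop
            lln = (_ll_newr_t(t, OM, pcap, newr)
                   + _pois(IY[t], q * OM[t]) + _pois(IA[t], (1.0 - q) * OM[t]))
            if math.log(np.random.random()) < lln - llo:
                acc_b[j] += 1.0
                if it >= n_burn:
                    acc[j] += 1.0
            else:
                x[j] = xo

        # ---- latent abundances and immigrant counts ----
        for blk in range(4):
            if blk == 0:
                o = off_NY
            elif blk == 1:
                o = off_NA
            elif blk == 2:
                o = off_IY
            else:
                o = off_IA
            t0 = 0 if blk < 2 else 1
            for t in range(t0, T):
                j = o + t
                xo = x[j]
                step = np.random.normal() * scales[j]
                d = float(round(step))
                if d == 0.0:
                    d = 1.0 if np.random.random() < 0.5 else -1.0
                prop = xo + d
                tries_b[j] += 1.0
                if it >= n_burn:
                    tries[j] += 1.0
                if prop < 0.0:
                    continue
                if blk < 2 and t == 0 and prop > nmax:
                    continue
                llo = 0.0
                if blk < 2:
                    llo += _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                        PNS, SNY, SNA, firstcl, eggs, fled)
                if t >= 1:
                    llo += _ll_trans_t(t, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                if blk < 2 and t + 1 < T:
                    llo += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                x[j] = prop
                lln = 0.0
                if blk < 2:
                    lln += _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                        PNS, SNY, SNA, firstcl, eggs, fled)
                if t >= 1:
                    lln += _ll_trans_t(t, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                if blk < 2 and t + 1 < T:
                    lln += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                       pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                       SJ, SAr)
                if math.log(np.random.random()) < lln - llo:
                    acc_b[j] += 1.0
                    if it >= n_burn:
                        acc[j] += 1.0
                else:
                    x[j] = xo

        # ---- imputed covariates ----
        k = off_imp
        for i in range(imp_rh.shape[0]):
            t = imp_rh[i]
            j = k + i
            xo = x[j]
            prop = xo + np.random.normal() * scales[j]
            tries_b[j] += 1.0
            if it >= n_burn:
                tries[j] += 1.0
            llo = (_ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
                   + _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                  PNS, SNY, SNA, firstcl, eggs, fled)
                   - 0.5 * xo * xo)
            if t + 1 < T:
                llo += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            x[j] = prop
            rainh[t] = prop
            _refresh_pNS(x, t, t + 1, rainh, temph, PNS)
            _refresh_sN(x, t, t + 1, rainh, temph, SNY, SNA)
            lln = (_ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
                   + _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                  PNS, SNY, SNA, firstcl, eggs, fled)
                   - 0.5 * prop * prop)
            if t + 1 < T:
                lln += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            if math.log(np.random.random()) < lln - llo:
                acc_b[j] += 1.0
                if it >= n_burn:
                    acc[j] += 1.0
            else:
                x[j] = xo
                rainh[t] = xo
                _refresh_pNS(x, t, t + 1, rainh, temph, PNS)
                _refresh_sN(x, t, t + 1, rainh, temph, SNY, SNA)
        k += imp_rh.shape[0]
        for i in range(imp_th.shape[0]):
            t = imp_th[i]
            j = k + i
            xo = x[j]
            prop = xo + np.random.normal() * scales[j]
            tries_b[j] += 1.0
            if it >= n_burn:
                tries[j] += 1.0
            llo = (_ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
                   + _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                  PNS, SNY, SNA, firstcl, eggs, fled)
                   - 0.5 * xo * xo)
            if t + 1 < T:
                llo += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            x[j] = prop
            temph[t] = prop
            _refresh_pNS(x, t, t + 1, rainh, temph, PNS)
            _refresh_sN(x, t, t + 1, rainh, temph, SNY, SNA)
            lln = (_ll_nest_t(t, PNS, SNY, SNA, nsucc, sumf, sumcf, failc)
                   + _ll_counts_t(t, NY[t], NA[t], pBY, pBA, CSY, CSA,
                                  PNS, SNY, SNA, firstcl, eggs, fled)
                   - 0.5 * prop * prop)
            if t + 1 < T:
                lln += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            if math.log(np.random.random()) < lln - llo:
                acc_b[j] += 1.0
                if it >= n_burn:
                    acc[j] += 1.0
            else:
                x[j] = xo
                temph[t] = xo
                _refresh_pNS(x, t, t + 1, rainh, temph, PNS)
                _refresh_sN(x, t, t + 1, rainh, temph, SNY, SNA)
        k += imp_th.shape[0]
        for i in range(imp_rf.shape[0]):
            t = imp_rf[i]
            j = k + i
            xo = x[j]
            prop = xo + np.random.normal() * scales[j]
            tries_b[j] += 1.0
            if it >= n_burn:
                tries[j] += 1.0
            llo = -0.5 * xo * xo
            if t < T - 1:
                llo += _ll_cjs_juv_row(t, act_j, m_j, nv_j, SJ, SAr, PY, PA)
            if t + 1 < T:
                llo += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            x[j] = prop
            rainf[t] = prop
            _refresh_sJ(x, t, t + 1, rainf, SJ)
            lln = -0.5 * prop * prop
            if t < T - 1:
                lln += _ll_cjs_juv_row(t, act_j, m_j, nv_j, SJ, SAr, PY, PA)
            if t + 1 < T:
                lln += _ll_trans_t(t + 1, NY, NA, IY, IA, OM, x[I_Q],
                                   pBY, pBA, CSY, CSA, PNS, SNY, SNA,
                                   SJ, SAr)
            if math.log(np.random.random()) < lln - llo:
                acc_b[j] += 1.0
                if it >= n_burn:
                    acc[j] += 1.0
            else:
                x[j] = xo
                rainf[t] = xo
                _refresh_sJ(x, t, t + 1, rainf, SJ)

        # ---- burn-in batch adaptation (frozen afterwards) ----
        if it < n_burn and (it + 1) % 50 == 0:
            for j in range(n_par):
                if tries_b[j] > 0.0:
                    rate = acc_b[j] / tries_b[j]
                    if rate > 0.44:
                        scales[j] *= 1.12
                    else:
                        scales[j] /= 1.12
                    if scales[j] < 1e-3:
                        scales[j] = 1e-3
                    if scales[j] > 50.0:
                        scales[j] = 50.0
                acc_b[j] = 0.0
                tries_b[j] = 0.0

        if it >= n_burn and (it - n_burn + 1) % thin == 0:
            for j in range(n_par):
                draws[kept, j] = x[j]
            kept += 1

    rates_out = np.zeros(n_par)
    for j in range(n_par):
        if tries[j] > 0.0:
            rates_out[j] = acc[j] / tries[j]
    return draws[:kept], rates_out
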