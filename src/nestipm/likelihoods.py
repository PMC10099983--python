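"""Log-likelihood components of the integrated population model.

Every data stream contributes an additive log-likelihood term:

* mark–recapture histories — an age-structured Cormack–Jolly–Seber (CJS)
  model in which the recapture probability factors as
  ``p[a, t] = pB[a, t] * pCapB[t]`` (breeding probability times the
  probability of capture and identification given breeding in a nestbox);
* individual clutch sizes of known-age mothers — Poisson;
* individual nest fates — a mixture separating complete nest failure
  (probability ``1 - pNS``) from per-egg losses (``sN``), so a zero-fledged
  nest can arise either way;
* annual population-level counts — Poisson observations around the latent
  expectations;
* latent state transitions — Poisson recruitment and Binomial adult survival
  around the age-structured projection.

These numpy/scipy implementations are the reference used in tests and by the
independent (single-component) fits; the MCMC engine mirrors them on
sufficient statistics for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core import AGE_ADULT, AGE_YEARLING, VitalRateSeries
from .io import CaptureHistories

__all__ = [
    "LinkModel",
    "ParameterSet",
    "linear_predictor",
    "cjs_loglik",
    "build_marrays",
    "marray_loglik",
    "clutch_loglik",
    "nest_fate_loglik",
    "counts_loglik",
    "state_transition_loglik",
]

_TINY = 1e-300


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _invlogit(x):
    return special.expit(x)


@dataclass
class LinkModel:
    """Link-scale linear model for one vital rate.

    ``intercept`` holds one value per age class on the link scale (a scalar
    for rates without age structure). Covariate slopes are per SD of the
    standardized covariate and are present only for rates the model gives an
    environmental effect (rain/temperature on nest success and nestling
    survival, post-fledging rain on juvenile survival); ``None`` means the
    term is absent. ``eps`` are year random effects, normal on the link scale
    with SD ``sigma``.
    """

    intercept: np.ndarray | float
    link: str = "logit"          # "logit" for probabilities, "log" for clutch size
    beta_rain: float | None = None
    beta_temp: float | None = None
    eps: np.ndarray | None = None
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.link not in ("logit", "log"):
            raise ValueError("link must be 'logit' or 'log'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def linear_predictor(model: LinkModel, age: int, year: int,
                     covariates: dict | None = None) -> float:
    """Vital rate on the natural scale for one age class and year.

    ``covariates`` maps "rain"/"temp" to the standardized value for the year;
    terms whose slope is absent contribute nothing. A slope with a missing
    covariate value is an error — imputation is the inference engine's job.
    """
    intercept = np.atleast_1d(np.asarray(model.intercept, dtype=float))
    eta = intercept[age] if intercept.size > 1 else intercept[0]
    covariates = covariates or {}
    for slope, key in ((model.beta_rain, "rain"), (model.beta_temp, "temp")):
        if slope is None:
            continue
        value = covariates.get(key)
        if value is None or np.isnan(value):
            raise ValueError(
                f"covariate {key!r} required by the model is missing for year {year}"
            )
        eta += slope * value
    if model.eps is not None:
        eta += model.eps[year]
    return float(_invlogit(eta) if model.link == "logit" else np.exp(eta))


@dataclass
class ParameterSet:
    """Link models for every vital rate plus expected immigrant counts."""

    pB: LinkModel
    CS: LinkModel
    pNS: LinkModel
    sN: LinkModel
    sJ: LinkModel
    sA: LinkModel
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 0)))  # (2, T)

    def vital_rates(self, covariates: dict[str, np.ndarray], n_years: int,
                    cs_max: float = 20.0) -> VitalRateSeries:
        """Materialize the year-by-year :class:`VitalRateSeries`.

        ``covariates`` maps "rain_hatch"/"temp_hatch"/"rain_fledge" to
        standardized per-year arrays (only needed for rates whose slopes are
        present).
        """
        def series(model, ages, rain_key=None, temp_key=None):
            rain = covariates.get(rain_key) if rain_key else None
            temp = covariates.get(temp_key) if temp_key else None
            out = np.empty((len(ages), n_years))
            for i, a in enumerate(ages):
                for t in range(n_years):
                    cv = {"rain": rain[t] if rain is not None else None,
                          "temp": temp[t] if temp is not None else None}
                    out[i, t] = linear_predictor(model, a, t, cv)
            return out

        return VitalRateSeries(
            pB=series(self.pB, (0, 1)), CS=series(self.CS, (0, 1)),
            pNS=series(self.pNS, (0,), "rain_hatch", "temp_hatch")[0],
            sN=series(self.sN, (0, 1), "rain_hatch", "temp_hatch"),
            sJ=series(self.sJ, (0,), "rain_fledge")[0],
            sA=series(self.sA, (0,))[0],
            cs_max=cs_max,
        )


def _check_probs(**named) -> None:
    for name, arr in named.items():
        a = np.asarray(arr, dtype=float)
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError(f"{name} outside [0, 1]")


def cjs_loglik(histories: CaptureHistories, sJ, sA, pB, pCapB) -> float:
    """Age-structured CJS log-likelihood over individual capture histories.

    Nestling-ringed individuals survive their first interval with ``sJ[t]``
    and are yearlings at their first anniversary (recapture probability
    ``pB[yearling] * pCapB``), adults thereafter; adult-ringed individuals use
    adult rates throughout. Detection histories are conditioned on first
    capture and closed with the standard never-seen-again terms. Equals the
    m-array multinomial likelihood on the same data.
    """
    sJ = np.asarray(sJ, dtype=float)
    sA = np.asarray(sA, dtype=float)
    pB = np.atleast_2d(np.asarray(pB, dtype=float))
    pCapB = np.asarray(pCapB, dtype=float)
    _check_probs(sJ=sJ, sA=sA, pB=pB, pCapB=pCapB)
    T = pCapB.size
    p_y = pB[AGE_YEARLING] * pCapB
    p_a = pB[AGE_ADULT] * pCapB

    # chi_adult[t]: P(an adult alive at occasion t is never seen again)
    chi_a = np.ones(T)
    for t in range(T - 2, -1, -1):
        chi_a[t] = 1.0 - sA[t] + sA[t] * (1.0 - p_a[t + 1]) * chi_a[t + 1]

    total = 0.0
    for i in range(len(histories)):
        f = int(histories.first_year[i])
        det = histories.detections[i]
        juv = histories.ring_age[i] == "nestling"
        seen = np.nonzero(det)[0]
        last = int(seen[-1])
        ll = 0.0
        for t in range(f, last):
            s = sJ[t] if (juv and t == f) else sA[t]
            p = p_y[t + 1] if (juv and t + 1 == f + 1) else p_a[t + 1]
            ll += np.log(max(s, _TINY))
            ll += np.log(max(p if det[t + 1] else 1.0 - p, _TINY))
        # never-seen-again closure from the last sighting
        if last < T - 1:
            if juv and last == f:
                chi = (1.0 - sJ[f]
                       + sJ[f] * (1.0 - p_y[f + 1]) * chi_a[f + 1])
            else:
                chi = chi_a[last]
            ll += np.log(max(chi, _TINY))
        total += ll
    return float(total)


def build_marrays(histories: CaptureHistories):
    """Reduce capture histories to age-structured m-arrays.

    Returns ``(m_juv, never_juv, m_ad, never_ad)``: ``m[r, c]`` counts
    individuals released at occasion r (as nestling-ringed first releases for
    the juvenile array, as adults — including re-releases — otherwise) and
    next recaptured at occasion c; ``never[r]`` counts releases never seen
    again.
    """
    T = len(histories.years)
    m_j = np.zeros((max(T - 1, 0), T), dtype=np.int64)
    nv_j = np.zeros(max(T - 1, 0), dtype=np.int64)
    m_a = np.zeros_like(m_j)
    nv_a = np.zeros_like(nv_j)
    for i in range(len(histories)):
        det = histories.detections[i]
        seen = np.nonzero(det)[0]
        juv = histories.ring_age[i] == "nestling"
        for k, r in enumerate(seen):
            if r == T - 1:
                continue
            as_juv = juv and k == 0
            m, nv = (m_j, nv_j) if as_juv else (m_a, nv_a)
            if k + 1 < len(seen):
                m[r, seen[k + 1]] += 1
            else:
                nv[r] += 1
    return m_j, nv_j, m_a, nv_a


def marray_loglik(m_juv, never_juv, m_ad, never_ad, sJ, sA, pB, pCapB) -> float:
    """Multinomial m-array log-likelihood (no combinatorial constants).

    Identical to :func:`cjs_loglik` on the same data: the product of ordered
    individual history probabilities equals the product of cohort cell
    probabilities.
    """
    sJ = np.asarray(sJ, dtype=float)
    sA = np.asarray(sA, dtype=float)
    pB = np.atleast_2d(np.asarray(pB, dtype=float))
    pCapB = np.asarray(pCapB, dtype=float)
    _check_probs(sJ=sJ, sA=sA, pB=pB, pCapB=pCapB)
    T = pCapB.size
    p_y = pB[AGE_YEARLING] * pCapB
    p_a = pB[AGE_ADULT] * pCapB
    ll = 0.0
    for m, never, juv in ((m_juv, never_juv, True), (m_ad, never_ad, False)):
        for r in range(T - 1):
            if never[r] == 0 and not m[r].any():
                continue
            cum = sJ[r] if juv else sA[r]
            seen_prob = 0.0
            for c in range(r + 1, T):
                p = p_y[c] if (juv and c == r + 1) else p_a[c]
                nu = cum * p
                if m[r, c]:
                    ll += m[r, c] * np.log(max(nu, _TINY))
                seen_prob += nu
                if c < T - 1:
                    cum *= (1.0 - p) * sA[c]
            if never[r]:
                ll += never[r] * np.log(max(1.0 - seen_prob, _TINY))
    return float(ll)


def clutch_loglik(age_idx, year_idx, clutch, CS) -> float:
    """Poisson log-likelihood of clutch sizes of known-age mothers.

    ``CS`` has shape (2, T) on the natural (eggs) scale. A vanishing mean with
    a positive clutch returns a large negative (finite) value.
    """
    age_idx = np.asarray(age_idx, dtype=int)
    year_idx = np.asarray(year_idx, dtype=int)
    clutch = np.asarray(clutch, dtype=int)
    if np.any(clutch < 1):
        raise ValueError("included clutch records must have clutch >= 1")
    mu = np.maximum(np.asarray(CS, dtype=float)[age_idx, year_idx], 1e-12)
    return float(stats.poisson.logpmf(clutch, mu).sum())


def nest_fate_loglik(age_idx, year_idx, clutch, fledged, pNS, sN) -> float:
    """Mixture log-likelihood of nest fates.

    A nest with ``fledged > 0`` contributes ``log[pNS * Binom(f | clutch,
    sN_a)]``; a zero-fledged nest folds complete failure and all-egg loss:
    ``log[(1 - pNS) + pNS * (1 - sN_a)^clutch]``.
    """
    age_idx = np.asarray(age_idx, dtype=int)
    year_idx = np.asarray(year_idx, dtype=int)
    clutch = np.asarray(clutch, dtype=int)
    fledged = np.asarray(fledged, dtype=int)
    if np.any(fledged > clutch):
        raise ValueError("fledged exceeds clutch size")
    pNS = np.asarray(pNS, dtype=float)
    sN = np.asarray(sN, dtype=float)
    _check_probs(pNS=pNS, sN=sN)
    pns = pNS[year_idx]
    sn = sN[age_idx, year_idx]
    out = np.where(
        fledged > 0,
        np.log(np.maximum(pns, _TINY))
        + stats.binom.logpmf(fledged, clutch, np.clip(sn, 1e-12, 1 - 1e-12)),
        np.log(np.maximum((1.0 - pns) + pns * (1.0 - sn) ** clutch, _TINY)),
    )
    return float(out.sum())


def _poisson_ll(obs, mu) -> float:
    obs = np.asarray(obs, dtype=float)
    mu = np.asarray(mu, dtype=float)
    ok = ~np.isnan(obs)
    return float(stats.poisson.logpmf(obs[ok].astype(int), mu[ok]).sum())


def counts_loglik(counts, N, params: "ParameterSet", rates: VitalRateSeries,
                  pCapB) -> float:
    """Poisson observation log-likelihood of the annual count streams.

    ``counts`` is a DataFrame with columns ``first_clutches``, ``eggs``,
    ``fledglings``, ``newly_ringed_adults`` (NaN = missing year); ``N`` the
    latent abundances (2, T). Expectations: breeders for first clutches, the
    fecundity chain for eggs/fledglings, and ``pCapB * sum_a omega[a, t]`` for
    newly ringed adults (year 0 has no immigration term and is skipped).
    """
    N = np.asarray(N, dtype=float)
    pCapB = np.asarray(pCapB, dtype=float)
    breeders = (N * rates.pB).sum(axis=0)
    eggs = (N * rates.pB * rates.CS).sum(axis=0)
    fled = (N * rates.pB * rates.CS * rates.pNS[None, :] * rates.sN).sum(axis=0)
    ll = _poisson_ll(counts["first_clutches"].to_numpy(), breeders)
    ll += _poisson_ll(counts["eggs"].to_numpy(), eggs)
    ll += _poisson_ll(counts["fledglings"].to_numpy(), fled)
    newr = counts["newly_ringed_adults"].to_numpy(dtype=float)
    om_tot = params.omega.sum(axis=0)
    ll += _poisson_ll(newr[1:], (pCapB * om_tot)[1:])
    return float(ll)


def state_transition_loglik(N, imm, rates: VitalRateSeries, omega) -> float:
    """Log-likelihood of the latent state transitions.

    For each interval t -> t+1: local recruits ``N_Y[t+1] - ImmY[t+1]`` are
    Poisson with mean ``0.5 * sJ[t] * sum_a N[a, t] * F[a, t]``; adult
    survivors ``N_A[t+1] - ImmA[t+1]`` are Binomial(Ntot[t], sA[t]);
    immigrant counts are Poisson with means ``omega[a, t+1]``. Impossible
    states (negative recruits, survivors exceeding Ntot) give -inf.
    """
    N = np.asarray(N, dtype=float)
    imm = np.asarray(imm, dtype=float)
    omega = np.asarray(omega, dtype=float)
    F = rates.fecundity()
    T = N.shape[1]

    def pois(k, mu):
        # a degenerate expectation only supports a zero count
        if mu <= 0.0:
            return 0.0 if k == 0 else float("-inf")
        return float(stats.poisson.logpmf(int(k), mu))

    ll = 0.0
    for t in range(T - 1):
        recruits = N[AGE_YEARLING, t + 1] - imm[AGE_YEARLING, t + 1]
        survivors = N[AGE_ADULT, t + 1] - imm[AGE_ADULT, t + 1]
        ntot = N[:, t].sum()
        if recruits < 0 or survivors < 0 or survivors > ntot:
            return float("-inf")
        mu_rec = 0.5 * rates.sJ[t] * (N[:, t] * F[:, t]).sum()
        ll += pois(recruits, mu_rec)
        ll += stats.binom.logpmf(int(survivors), int(ntot),
                                 np.clip(rates.sA[t], 0.0, 1.0))
        ll += pois(imm[AGE_YEARLING, t + 1], omega[AGE_YEARLING, t + 1])
        ll += pois(imm[AGE_ADULT, t + 1], omega[AGE_ADULT, t + 1])
        if not np.isfinite(ll):
            return float("-inf")
    return float(ll)
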