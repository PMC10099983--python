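"""Bayesian fitting of the integrated population model.

The joint posterior over vital-rate link models, expected immigrant counts
and latent age-structured abundances is sampled with an adaptive
Metropolis-within-Gibbs algorithm (single-site random walks, acceptance
tuned towards ~0.44 during burn-in, adaptation frozen afterwards). Priors
are noninformative with biologically sensible upper bounds; initial values
are simulated until the posterior density is finite; missing standardized
covariates are imputed as standard-normal latent draws within the model.

The module also provides the Gelman–Rubin convergence diagnostic, fits of
each data component on its own (for integrated-vs-independent comparisons),
posterior-predictive count tables, and stochastic forward projections from
posterior medians — the three-step model-testing procedure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import _mcmc, core
from . import io as nio
from . import likelihoods as lk

__all__ = [
    "FitConfig",
    "PriorSet",
    "IPMData",
    "PosteriorSamples",
    "InitializationError",
    "default_priors",
    "build_covariates",
    "build_ipm_data",
    "fit_ipm",
    "fit_independent",
    "gelman_rubin",
    "posterior_predictive_table",
    "forward_projection_check",
    "rates_from_draws",
    "theta_draws_from_samples",
]

TOP_NAMES = _mcmc.TOP_NAMES


class InitializationError(RuntimeError):
    """No finite-posterior starting state found after the retry budget."""


@dataclass(frozen=True)
class FitConfig:
    """MCMC run settings.

    The default profile runs four chains of 200,000 iterations with a
    50,000-iteration burn-in thinned to every 30th draw; the ``test_profile``
    is a reduced configuration for simulation studies and tests.
    """

    n_chains: int = 4
    n_iter: int = 200_000
    n_burnin: int = 50_000
    thin: int = 30
    seed: int = 1
    rhat_threshold: float = 1.1
    init_retries: int = 100
    prior_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def test_profile(cls, seed: int = 1, **kw) -> "FitConfig":
        return cls(n_chains=3, n_iter=20_000, n_burnin=5_000, thin=10,
                   seed=seed, **kw)


@dataclass
class PriorSet:
    """Uniform prior bounds for the top-level scalars plus derived bounds.

    ``lo``/``hi`` follow the parameter order of the sampler's scalar block;
    ``om_max`` bounds the yearly expected immigrant totals and ``nmax`` the
    initial abundances (both filled from the data when not overridden).
    """

    lo: np.ndarray
    hi: np.ndarray
    om_max: float | None = None
    nmax: float | None = None

    def bounds(self, name: str) -> tuple[float, float]:
        j = TOP_NAMES.index(name)
        return float(self.lo[j]), float(self.hi[j])


def default_priors(overrides: dict | None = None) -> PriorSet:
    """Noninformative priors with biologically sensible upper bounds.

    Probabilities (and the immigrant age mix q) are Uniform(0, 1); mean
    clutch sizes Uniform(0, 12); covariate slopes Uniform(-5, 5) on the link
    scale; year-effect SDs Uniform(0, 3). ``overrides`` maps parameter names
    to (lo, hi) pairs; an inverted pair is a configuration error.
    """
    lo = np.zeros(len(TOP_NAMES))
    hi = np.ones(len(TOP_NAMES))
    for j, name in enumerate(TOP_NAMES):
        if name.startswith("CS_"):
            hi[j] = 12.0
        elif name.startswith("beta_"):
            lo[j], hi[j] = -5.0, 5.0
        elif name.startswith("sigma_"):
            hi[j] = 3.0
    ps = PriorSet(lo=lo, hi=hi)
    for name, pair in (overrides or {}).items():
        if name == "om_max":
            ps.om_max = float(pair)
            continue
        if name == "nmax":
            ps.nmax = float(pair)
            continue
        if name not in TOP_NAMES:
            raise ValueError(f"unknown prior parameter {name!r}")
        a, b = float(pair[0]), float(pair[1])
        if a >= b:
            raise ValueError(f"inverted prior bounds for {name}: ({a}, {b})")
        j = TOP_NAMES.index(name)
        ps.lo[j], ps.hi[j] = a, b
    return ps


def build_covariates(nests: pd.DataFrame, env: nio.EnvSeries, years,
                     donor_windows: dict | None = None) -> dict:
    """Standardized annual covariates from nest phenology and daily weather.

    Per year the post-hatch and post-fledge windows are centred on the 0.25
    quantile of estimated hatch dates; a year without estimable windows
    borrows from ``donor_windows`` (year -> ((h0, h1), (f0, f1))) when given,
    otherwise its covariates stay missing (imputed during fitting). Returns
    standardized arrays plus window and standardization metadata.
    """
    axis = np.arange(years[0], years[1] + 1)
    raw = {k: np.full(len(axis), np.nan)
           for k in ("rain_hatch", "temp_hatch", "rain_fledge")}
    windows: dict[int, tuple] = {}
    usable = nests[nests["first_egg_doy"].notna() & (nests["clutch"] >= 1)]
    for i, year in enumerate(axis):
        sub = usable[usable["year"] == year]
        if len(sub):
            hatch = nio.hatch_date(sub["first_egg_doy"].to_numpy(),
                                   sub["clutch"].to_numpy())
            wh = nio.posthatch_window(hatch)
            wf = nio.postfledge_window(hatch)
        elif donor_windows and int(year) in donor_windows:
            wh, wf = donor_windows[int(year)]
        else:
            continue
        windows[int(year)] = (wh, wf)
        raw["rain_hatch"][i], _ = nio.aggregate_covariate(env, year, wh, "rain_mm")
        raw["temp_hatch"][i], _ = nio.aggregate_covariate(env, year, wh, "tmin_c")
        raw["rain_fledge"][i], _ = nio.aggregate_covariate(env, year, wf, "rain_mm")
    out: dict = {"windows": windows, "standardization": {}}
    for key, vals in raw.items():
        std, meta = nio.zstandardize(vals)
        out[key] = std
        out["standardization"][key] = meta
    return out


@dataclass
class IPMData:
    """Observation streams reduced to the sufficient statistics the sampler uses."""

    T: int
    years: np.ndarray
    # CJS m-arrays (float for numba) and row-activity flags
    m_j: np.ndarray
    nv_j: np.ndarray
    act_j: np.ndarray
    m_a: np.ndarray
    nv_a: np.ndarray
    act_a: np.ndarray
    # clutch statistics per (age, year)
    ncl: np.ndarray
    scl: np.ndarray
    # nest-fate statistics per (age, year) and failures by clutch size
    nsucc: np.ndarray
    sumf: np.ndarray
    sumcf: np.ndarray
    failc: np.ndarray
    # annual counts (NaN = missing)
    firstcl: np.ndarray
    eggs: np.ndarray
    fled: np.ndarray
    newr: np.ndarray
    pcap: np.ndarray
    # standardized covariates with missing values zeroed + their indices
    rainh: np.ndarray
    temph: np.ndarray
    rainf: np.ndarray
    imp_rh: np.ndarray
    imp_th: np.ndarray
    imp_rf: np.ndarray
    counts: pd.DataFrame | None = None
    histories: nio.CaptureHistories | None = None

    @property
    def n_imputed(self) -> int:
        return len(self.imp_rh) + len(self.imp_th) + len(self.imp_rf)


_AGE_IDX = {"yearling": 0, "adult": 1}


def build_ipm_data(nests: pd.DataFrame, histories: nio.CaptureHistories,
                   counts: pd.DataFrame, covariates: dict) -> IPMData:
    """Assemble the fitting bundle from validated tables.

    Individual clutch and nest-fate statistics use nests of known-age
    mothers only; population-level counts use all nests. Years with missing
    pCapB take the mean of the observed years (deterministic imputation).
    """
    years = counts.index.to_numpy()
    T = len(years)
    y0 = int(years[0])
    m_j, nv_j, m_a, nv_a = lk.build_marrays(histories)
    known = nests[nests["female_age"].isin(_AGE_IDX)]
    ncl = np.zeros((2, T))
    scl = np.zeros((2, T))
    nsucc = np.zeros((2, T))
    sumf = np.zeros((2, T))
    sumcf = np.zeros((2, T))
    cmax = int(known["clutch"].max()) if len(known) else 1
    failc = np.zeros((2, T, cmax + 1))
    for _, row in known.iterrows():
        a = _AGE_IDX[row["female_age"]]
        t = int(row["year"]) - y0
        if not 0 <= t < T or row["clutch"] < 1:
            continue
        ncl[a, t] += 1
        scl[a, t] += row["clutch"]
        if row["fledged"] > 0:
            nsucc[a, t] += 1
            sumf[a, t] += row["fledged"]
            sumcf[a, t] += row["clutch"] - row["fledged"]
        else:
            failc[a, t, int(row["clutch"])] += 1

    pcap = counts["pCapB"].to_numpy(dtype=float).copy()
    if np.isnan(pcap).any():
        pcap[np.isnan(pcap)] = np.nanmean(pcap)

    def _cov(key):
        arr = np.asarray(covariates[key], dtype=float).copy()
        idx = np.nonzero(np.isnan(arr))[0].astype(np.int64)
        arr[idx] = 0.0
        return arr, idx

    rainh, imp_rh = _cov("rain_hatch")
    temph, imp_th = _cov("temp_hatch")
    rainf, imp_rf = _cov("rain_fledge")

    return IPMData(
        T=T, years=years,
        m_j=m_j.astype(float), nv_j=nv_j.astype(float),
        act_j=(nv_j > 0) | m_j.any(axis=1),
        m_a=m_a.astype(float), nv_a=nv_a.astype(float),
        act_a=(nv_a > 0) | m_a.any(axis=1),
        ncl=ncl, scl=scl, nsucc=nsucc, sumf=sumf, sumcf=sumcf, failc=failc,
        firstcl=counts["first_clutches"].to_numpy(dtype=float),
        eggs=counts["eggs"].to_numpy(dtype=float),
        fled=counts["fledglings"].to_numpy(dtype=float),
        newr=counts["newly_ringed_adults"].to_numpy(dtype=float),
        pcap=pcap, rainh=rainh, temph=temph, rainf=rainf,
        imp_rh=imp_rh, imp_th=imp_th, imp_rf=imp_rf,
        counts=counts, histories=histories,
    )


def _resolve_priors(data: IPMData, config: FitConfig) -> PriorSet:
    ps = default_priors(config.prior_overrides)
    if ps.om_max is None:
        ps.om_max = 2.0 * float(np.nanmax(data.newr)) + 10.0
    if ps.nmax is None:
        ps.nmax = 4.0 * float(np.nanmax(data.firstcl)) + 40.0
    return ps


def _param_names(data: IPMData) -> list[str]:
    names = list(TOP_NAMES)
    for blk in ("eps_pB", "eps_CS", "eps_pNS", "eps_sN", "eps_sJ", "eps_sA",
                "Om", "NY", "NA", "IY", "IA"):
        names += [f"{blk}[{t}]" for t in range(data.T)]
    names += [f"imp_rain_hatch[{t}]" for t in data.imp_rh]
    names += [f"imp_temp_hatch[{t}]" for t in data.imp_th]
    names += [f"imp_rain_fledge[{t}]" for t in data.imp_rf]
    return names


def _manifest(data: IPMData) -> dict[str, str]:
    desc = {
        "pB_Y": "breeding probability, yearlings (intercept, natural scale)",
        "pB_A": "breeding probability, adults",
        "sigma_pB": "year-effect SD of breeding probability (logit scale)",
        "CS_Y": "mean clutch size, yearling mothers (eggs)",
        "CS_A": "mean clutch size, adult mothers (eggs)",
        "sigma_CS": "year-effect SD of clutch size (log scale)",
        "pNS": "nest success probability (intercept, natural scale)",
        "beta_rain_pNS": "post-hatch rain effect on nest success (logit/SD)",
        "beta_temp_pNS": "post-hatch temperature effect on nest success",
        "sigma_pNS": "year-effect SD of nest success (logit scale)",
        "sN_Y": "per-egg survival to fledging, yearling mothers",
        "sN_A": "per-egg survival to fledging, adult mothers",
        "beta_rain_sN": "post-hatch rain effect on nestling survival",
        "beta_temp_sN": "post-hatch temperature effect on nestling survival",
        "sigma_sN": "year-effect SD of nestling survival (logit scale)",
        "sJ": "apparent juvenile survival (intercept, natural scale)",
        "beta_rain_sJ": "post-fledging rain effect on juvenile survival",
        "sigma_sJ": "year-effect SD of juvenile survival (logit scale)",
        "sA": "apparent yearling/adult survival (intercept, natural scale)",
        "sigma_sA": "year-effect SD of adult survival (logit scale)",
        "q": "yearling share of expected immigrants",
    }
    blocks = {
        "eps_pB": "year random effect, breeding probability",
        "eps_CS": "year random effect, clutch size",
        "eps_pNS": "year random effect, nest success",
        "eps_sN": "year random effect, nestling survival",
        "eps_sJ": "year random effect, juvenile survival",
        "eps_sA": "year random effect, adult survival",
        "Om": "expected total immigrants entering before the census",
        "NY": "latent yearling females at the census",
        "NA": "latent adult females at the census",
        "IY": "latent immigrant yearlings",
        "IA": "latent immigrant adults",
        "imp_rain_hatch": "imputed standardized post-hatch rain",
        "imp_temp_hatch": "imputed standardized post-hatch temperature",
        "imp_rain_fledge": "imputed standardized post-fledge rain",
    }
    return {**desc, **blocks}


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with a parameter manifest.

    ``draws`` has shape (n_chains, n_kept, n_params); ``names`` orders the
    parameter axis. ``flagged_chains`` lists chains excluded from summaries
    for failing convergence.
    """

    names: list[str]
    draws: np.ndarray
    manifest: dict[str, str]
    years: np.ndarray
    config: FitConfig | None = None
    flagged_chains: list[int] = field(default_factory=list)
    acc_rates: np.ndarray | None = None

    @property
    def T(self) -> int:
        return len(self.years)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str, active_only: bool = True) -> np.ndarray:
        """Draws for one parameter, shape (n_chains_used, n_kept)."""
        arr = self.draws[:, :, self.index(name)]
        if active_only and self.flagged_chains:
            keep = [c for c in range(self.n_chains)
                    if c not in self.flagged_chains]
            arr = arr[keep]
        return arr

    def active(self) -> np.ndarray:
        """All draws from non-flagged chains, shape (D, n_params)."""
        keep = [c for c in range(self.n_chains) if c not in self.flagged_chains]
        return self.draws[keep].reshape(-1, self.draws.shape[2])

    def median(self, name: str) -> float:
        return float(np.median(self.get(name)))

    def ci(self, name: str, level: float = 0.95):
        arr = self.get(name).ravel()
        a = (1.0 - level) / 2.0
        return float(np.quantile(arr, a)), float(np.quantile(arr, 1.0 - a))

    def summary(self, names=None) -> pd.DataFrame:
        names = list(names) if names is not None else self.names
        rows = []
        for n in names:
            lo, hi = self.ci(n)
            rows.append((n, self.median(n), lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "median",
                                           "lower95", "upper95"])

    def to_dir(self, path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for c in range(self.n_chains):
            pd.DataFrame(self.draws[c], columns=self.names).to_csv(
                out / f"chain_{c}.csv", index=False)
        meta = {
            "names": self.names, "manifest": self.manifest,
            "years": [int(y) for y in self.years],
            "flagged_chains": self.flagged_chains,
            "n_chains": self.n_chains,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        self.summary(list(TOP_NAMES)).to_csv(out / "summary.csv", index=False)

    @classmethod
    def from_dir(cls, path) -> "PosteriorSamples":
        p = Path(path)
        with open(p / "manifest.json") as fh:
            meta = json.load(fh)
        chains = [pd.read_csv(p / f"chain_{c}.csv").to_numpy()
                  for c in range(meta["n_chains"])]
        return cls(names=meta["names"], draws=np.stack(chains),
                   manifest=meta["manifest"],
                   years=np.asarray(meta["years"]),
                   flagged_chains=meta["flagged_chains"])


def gelman_rubin(samples, names=None):
    """Gelman–Rubin potential scale reduction factor.

    ``R_hat = sqrt(((n-1)/n * W + B/n) / W)`` with W the mean within-chain
    variance and B/n the between-chain variance of chain means. Accepts a
    (n_chains, n_draws) array (returns a float) or a
    :class:`PosteriorSamples` (returns a dict over ``names``, default the
    top-level parameters). Requires >= 2 chains and >= 10 retained draws.
    """
    if isinstance(samples, PosteriorSamples):
        names = list(names) if names is not None else list(TOP_NAMES)
        return {n: gelman_rubin(samples.get(n, active_only=False))
                for n in names}
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need draws from at least two chains "
                         "(run a multi-chain fit)")
    m, n = arr.shape
    if n < 10:
        raise ValueError("need at least 10 retained draws per chain")
    W = arr.var(axis=1, ddof=1).mean()
    B_over_n = arr.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def _flag_chains(draws: np.ndarray, names: list[str],
                 threshold: float) -> list[int]:
    """Leave-one-out heuristic: flag a single chain whose removal restores
    convergence of the top-level parameters."""
    if draws.shape[0] < 2:
        return []
    top = [names.index(n) for n in TOP_NAMES]

    def frac_bad(sub):
        bad = 0
        for j in top:
            if gelman_rubin(sub[:, :, j]) >= threshold:
                bad += 1
        return bad / len(top)

    if frac_bad(draws) <= 0.05:
        return []
    if draws.shape[0] < 3:
        return []
    best, best_frac = None, frac_bad(draws)
    for c in range(draws.shape[0]):
        keep = [i for i in range(draws.shape[0]) if i != c]
        f = frac_bad(draws[keep])
        if f < best_frac:
            best, best_frac = c, f
    return [best] if best is not None and best_frac <= 0.05 else []


def _initial_state(data: IPMData, priors: PriorSet, rng) -> np.ndarray:
    T = data.T
    x = np.zeros(_mcmc.n_params(T, data.n_imputed))
    off = _mcmc.block_offsets(T)
    x[_mcmc.I_PBY] = rng.uniform(0.4, 0.8)
    x[_mcmc.I_PBA] = rng.uniform(0.6, 0.95)
    x[_mcmc.I_CSY] = rng.uniform(4.5, 7.5)
    x[_mcmc.I_CSA] = rng.uniform(4.5, 7.5)
    x[_mcmc.I_PNS] = rng.uniform(0.6, 0.95)
    x[_mcmc.I_SNY] = rng.uniform(0.6, 0.95)
    x[_mcmc.I_SNA] = rng.uniform(0.6, 0.95)
    x[_mcmc.I_SJ] = rng.uniform(0.05, 0.3)
    x[_mcmc.I_SA] = rng.uniform(0.3, 0.7)
    x[_mcmc.I_Q] = rng.uniform(0.05, 0.5)
    for j in (_mcmc.I_BR_PNS, _mcmc.I_BT_PNS, _mcmc.I_BR_SN,
              _mcmc.I_BT_SN, _mcmc.I_BR_SJ):
        x[j] = rng.normal(0.0, 0.1)
    for j in (_mcmc.I_SIG_PB, _mcmc.I_SIG_CS, _mcmc.I_SIG_PNS,
              _mcmc.I_SIG_SN, _mcmc.I_SIG_SJ, _mcmc.I_SIG_SA):
        x[j] = rng.uniform(0.05, 0.5)
    for blk in ("eps_pB", "eps_CS", "eps_pNS", "eps_sN", "eps_sJ", "eps_sA"):
        x[off[blk]:off[blk] + T] = rng.normal(0.0, 0.02, size=T)

    firstcl = np.nan_to_num(data.firstcl, nan=float(np.nanmean(data.firstcl)))
    ntot = np.maximum(np.round(firstcl / x[_mcmc.I_PBA]), 2.0)
    ntot = np.minimum(ntot, priors.nmax)
    ny = np.round(0.35 * ntot)
    na = ntot - ny
    newr = np.nan_to_num(data.newr, nan=0.0)
    om = np.clip(newr / np.maximum(data.pcap, 0.2), 1.0, priors.om_max - 1.0)
    iy = np.minimum(np.round(x[_mcmc.I_Q] * om), ny)
    ia = np.minimum(np.round((1 - x[_mcmc.I_Q]) * om), na)
    # keep survivor counts feasible (<= previous total)
    for t in range(1, T):
        max_sur = ny[t - 1] + na[t - 1]
        if na[t] - ia[t] > max_sur:
            ia[t] = na[t] - max_sur
    iy[0] = ia[0] = 0.0
    x[off["Om"]:off["Om"] + T] = om
    x[off["NY"]:off["NY"] + T] = ny
    x[off["NA"]:off["NA"] + T] = na
    x[off["IY"]:off["IY"] + T] = iy
    x[off["IA"]:off["IA"] + T] = ia
    x[off["imputed"]:] = rng.normal(0.0, 0.3, size=data.n_imputed)
    return x


def _default_scales(data: IPMData) -> np.ndarray:
    T = data.T
    scales = np.empty(_mcmc.n_params(T, data.n_imputed))
    scales[:_mcmc.N_SCALAR] = 0.05
    off = _mcmc.block_offsets(T)
    for blk in ("eps_pB", "eps_CS", "eps_pNS", "eps_sN", "eps_sJ", "eps_sA"):
        scales[off[blk]:off[blk] + T] = 0.15
    scales[off["Om"]:off["Om"] + T] = 5.0
    for blk in ("NY", "NA", "IY", "IA"):
        scales[off[blk]:off[blk] + T] = 3.0
    scales[off["imputed"]:] = 0.5
    return scales


def _chain_args(data: IPMData, priors: PriorSet):
    return (data.act_j, data.m_j, data.nv_j, data.act_a, data.m_a, data.nv_a,
            data.ncl, data.scl, data.nsucc, data.sumf, data.sumcf, data.failc,
            data.firstcl, data.eggs, data.fled, data.newr, data.pcap)


def log_posterior(x: np.ndarray, data: IPMData, priors: PriorSet) -> float:
    """Joint log posterior density at one parameter state (for tests/inits)."""
    return float(_mcmc.full_log_post(
        x, *_chain_args(data, priors),
        data.rainh, data.temph, data.rainf,
        data.imp_rh, data.imp_th, data.imp_rf,
        priors.lo, priors.hi, priors.om_max, priors.nmax))


def fit_ipm(data: IPMData, config: FitConfig | None = None) -> PosteriorSamples:
    """Fit the integrated model by adaptive Metropolis-within-Gibbs MCMC.

    Chains run sequentially with seeds ``base seed + chain index``; results
    are bit-identical under a fixed configuration. Chains failing the
    Gelman–Rubin criterion (leave-one-out heuristic) are flagged and
    excluded from summaries.
    """
    config = config or FitConfig()
    if data.T < 5:
        raise ValueError("need at least five study years to fit the model")
    priors = _resolve_priors(data, config)
    names = _param_names(data)
    chains = []
    accs = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(config.seed * 1000 + c)
        x = None
        for _ in range(config.init_retries):
            cand = _initial_state(data, priors, rng)
            if np.isfinite(log_posterior(cand, data, priors)):
                x = cand
                break
        if x is None:
            raise InitializationError(
                f"no finite starting state for chain {c} after "
                f"{config.init_retries} retries")
        rainh = data.rainh.copy()
        temph = data.temph.copy()
        rainf = data.rainf.copy()
        off = _mcmc.block_offsets(data.T)
        k = off["imputed"]
        for i, t in enumerate(data.imp_rh):
            rainh[t] = x[k + i]
        k += len(data.imp_rh)
        for i, t in enumerate(data.imp_th):
            temph[t] = x[k + i]
        k += len(data.imp_th)
        for i, t in enumerate(data.imp_rf):
            rainf[t] = x[k + i]
        draws, acc = _mcmc.run_chain(
            x, _default_scales(data), config.n_iter, config.n_burnin,
            config.thin, int(config.seed) + c,
            *_chain_args(data, priors),
            rainh, temph, rainf, data.imp_rh, data.imp_th, data.imp_rf,
            priors.lo, priors.hi, priors.om_max, priors.nmax)
        chains.append(draws)
        accs.append(acc)
    draws = np.stack(chains)
    samples = PosteriorSamples(
        names=names, draws=draws, manifest=_manifest(data),
        years=data.years, config=config, acc_rates=np.stack(accs))
    samples.flagged_chains = _flag_chains(draws, names,
                                          config.rhat_threshold)
    return samples


def bundle_from_tables(nests: pd.DataFrame, histories: nio.CaptureHistories,
                       env: nio.EnvSeries, years: tuple[int, int],
                       donor_windows: dict | None = None) -> IPMData:
    """Assemble the fitting bundle from validated in-memory tables."""
    counts = nio.build_population_counts(nests, histories, years=years)
    cov = build_covariates(nests, env, years, donor_windows=donor_windows)
    return build_ipm_data(nests, histories, counts, cov)


def load_dataset_dir(path, years: tuple[int, int] | None = None,
                     donor_windows: dict | None = None) -> IPMData:
    """Read ``nests.csv``, ``captures.csv`` and ``weather.csv`` from a
    directory and assemble the fitting bundle."""
    p = Path(path)
    nests = nio.read_nest_table(p / "nests.csv")
    if years is None:
        lo = int(nests.frame["year"].min())
        hi = int(nests.frame["year"].max())
        years = (lo, hi)
    hist = nio.read_capture_table(p / "captures.csv", years=years)
    env = nio.read_weather_table(p / "weather.csv")
    return bundle_from_tables(nests.frame, hist, env, years,
                              donor_windows=donor_windows)


# ---------------------------------------------------------------------------
# independent single-component fits
# ---------------------------------------------------------------------------

_INDEPENDENT = ("cjs", "clutch", "nestfate")


def _mh_sampler(logpost, x0, scales, n_iter, n_burn, thin, seed,
                lo=None, hi=None):
    """Generic single-site adaptive MH on a small parameter vector."""
    rng = np.random.default_rng(seed)
    x = x0.copy()
    n = len(x)
    sc = scales.copy()
    ll = logpost(x)
    kept = []
    acc = np.zeros(n)
    tries = np.zeros(n)
    for it in range(n_iter):
        for j in range(n):
            prop = x[j] + rng.normal() * sc[j]
            if lo is not None and (prop <= lo[j] or prop >= hi[j]):
                tries[j] += 1
                continue
            xo = x[j]
            x[j] = prop
            lln = logpost(x)
            tries[j] += 1
            if np.log(rng.random()) < lln - ll:
                ll = lln
                acc[j] += 1
            else:
                x[j] = xo
        if it < n_burn and (it + 1) % 50 == 0:
            rate = np.where(tries > 0, acc / np.maximum(tries, 1), 0.44)
            sc *= np.where(rate > 0.44, 1.12, 1 / 1.12)
            sc = np.clip(sc, 1e-3, 50.0)
            acc[:] = 0
            tries[:] = 0
        if it >= n_burn and (it - n_burn + 1) % thin == 0:
            kept.append(x.copy())
    return np.asarray(kept)


def fit_independent(data: IPMData, which: str,
                    config: FitConfig | None = None) -> PosteriorSamples:
    """Fit one data component alone with the same likelihood and priors.

    ``which`` is one of ``cjs`` (mark–recapture: survival, breeding
    probability and their year effects), ``clutch`` (clutch-size model) or
    ``nestfate`` (nest success and nestling survival). Output parameter
    names align with the integrated-model manifest for overlap comparisons.
    """
    if which not in _INDEPENDENT:
        raise ValueError(f"unsupported component {which!r}; "
                         f"choose one of: {', '.join(_INDEPENDENT)}")
    config = config or FitConfig.test_profile()
    T = data.T
    rainh, temph, rainf = data.rainh, data.temph, data.rainf

    if which == "clutch":
        if data.ncl.sum() == 0:
            raise ValueError("no clutch records of known-age mothers")
        names = ["CS_Y", "CS_A", "sigma_CS"] + [f"eps_CS[{t}]" for t in range(T)]
        lo = np.r_[0.0, 0.0, 0.0, np.full(T, -np.inf)]
        hi = np.r_[12.0, 12.0, 3.0, np.full(T, np.inf)]

        def logpost(z):
            csy = np.exp(np.log(z[0]) + z[3:])
            csa = np.exp(np.log(z[1]) + z[3:])
            ll = np.sum(data.scl[0] * np.log(csy) - data.ncl[0] * csy)
            ll += np.sum(data.scl[1] * np.log(csa) - data.ncl[1] * csa)
            sg = z[2]
            return ll - T * np.log(sg) - 0.5 * np.sum(z[3:] ** 2) / sg**2

        x0 = np.r_[6.0, 6.0, 0.2, np.zeros(T)]
        sc = np.r_[0.1, 0.1, 0.05, np.full(T, 0.1)]
    elif which == "nestfate":
        if (data.nsucc.sum() + data.failc.sum()) == 0:
            raise ValueError("no nest-fate records of known-age mothers")
        names = (["pNS", "beta_rain_pNS", "beta_temp_pNS", "sigma_pNS",
                  "sN_Y", "sN_A", "beta_rain_sN", "beta_temp_sN", "sigma_sN"]
                 + [f"eps_pNS[{t}]" for t in range(T)]
                 + [f"eps_sN[{t}]" for t in range(T)])
        lo = np.r_[0.0, -5.0, -5.0, 0.0, 0.0, 0.0, -5.0, -5.0, 0.0,
                   np.full(2 * T, -np.inf)]
        hi = np.r_[1.0, 5.0, 5.0, 3.0, 1.0, 1.0, 5.0, 5.0, 3.0,
                   np.full(2 * T, np.inf)]
        cvals = np.arange(data.failc.shape[2])

        def logpost(z):
            pns = special.expit(special.logit(z[0]) + z[1] * rainh
                                + z[2] * temph + z[9:9 + T])
            ll = 0.0
            for a, sn0 in ((0, z[4]), (1, z[5])):
                sn = special.expit(special.logit(sn0) + z[6] * rainh
                                   + z[7] * temph + z[9 + T:9 + 2 * T])
                ll += np.sum(data.nsucc[a] * np.log(pns)
                             + data.sumf[a] * np.log(sn)
                             + data.sumcf[a] * np.log1p(-sn))
                mix = (1 - pns)[:, None] + pns[:, None] * \
                    (1 - sn)[:, None] ** cvals[None, :]
                ll += np.sum(data.failc[a] * np.log(np.maximum(mix, 1e-300)))
            for sg, sl in ((z[3], slice(9, 9 + T)),
                           (z[8], slice(9 + T, 9 + 2 * T))):
                ll += -T * np.log(sg) - 0.5 * np.sum(z[sl] ** 2) / sg**2
            return ll

        x0 = np.r_[0.8, 0.0, 0.0, 0.2, 0.8, 0.85, 0.0, 0.0, 0.2,
                   np.zeros(2 * T)]
        sc = np.r_[np.full(9, 0.05), np.full(2 * T, 0.1)]
    else:  # cjs
        if data.m_j.sum() + data.m_a.sum() + data.nv_j.sum() + data.nv_a.sum() == 0:
            raise ValueError("no capture histories")
        names = (["sJ", "beta_rain_sJ", "sigma_sJ", "sA", "sigma_sA",
                  "pB_Y", "pB_A", "sigma_pB"]
                 + [f"eps_sJ[{t}]" for t in range(T)]
                 + [f"eps_sA[{t}]" for t in range(T)]
                 + [f"eps_pB[{t}]" for t in range(T)])
        lo = np.r_[0.0, -5.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                   np.full(3 * T, -np.inf)]
        hi = np.r_[1.0, 5.0, 3.0, 1.0, 3.0, 1.0, 1.0, 3.0,
                   np.full(3 * T, np.inf)]

        def logpost(z):
            sj = special.expit(special.logit(z[0]) + z[1] * rainf
                               + z[8:8 + T])
            sa = special.expit(special.logit(z[3]) + z[8 + T:8 + 2 * T])
            pby = special.expit(special.logit(z[5]) + z[8 + 2 * T:])
            pba = special.expit(special.logit(z[6]) + z[8 + 2 * T:])
            ll = _mcmc._ll_cjs(data.act_j, data.m_j, data.nv_j,
                               data.act_a, data.m_a, data.nv_a,
                               sj, sa, pby * data.pcap, pba * data.pcap)
            for sg, sl in ((z[2], slice(8, 8 + T)),
                           (z[4], slice(8 + T, 8 + 2 * T)),
                           (z[7], slice(8 + 2 * T, 8 + 3 * T))):
                ll += -T * np.log(sg) - 0.5 * np.sum(z[sl] ** 2) / sg**2
            return ll

        x0 = np.r_[0.15, 0.0, 0.2, 0.5, 0.2, 0.6, 0.85, 0.2, np.zeros(3 * T)]
        sc = np.r_[np.full(8, 0.05), np.full(3 * T, 0.15)]

    chains = []
    for c in range(config.n_chains):
        kept = _mh_sampler(logpost, x0, sc, config.n_iter, config.n_burnin,
                           config.thin, config.seed * 1000 + 7 * c + 1,
                           lo=lo, hi=hi)
        chains.append(kept)
    return PosteriorSamples(names=names, draws=np.stack(chains),
                            manifest={n: f"independent {which} fit"
                                      for n in names},
                            years=data.years, config=config)


# ---------------------------------------------------------------------------
# posterior post-processing
# ---------------------------------------------------------------------------

def rates_from_draws(samples: PosteriorSamples, data: IPMData) -> dict:
    """Vectorized natural-scale rates and latents per active draw.

    Returns arrays of shape (D, T) for every vital rate plus latent
    abundances, immigrant counts and expected immigrant totals.
    """
    x = samples.active()
    T = samples.T
    off = _mcmc.block_offsets(T)

    def blk(name):
        return x[:, off[name]:off[name] + T]

    rainh = np.tile(data.rainh, (x.shape[0], 1))
    temph = np.tile(data.temph, (x.shape[0], 1))
    rainf = np.tile(data.rainf, (x.shape[0], 1))
    k = off["imputed"]
    for i, t in enumerate(data.imp_rh):
        rainh[:, t] = x[:, k + i]
    k += len(data.imp_rh)
    for i, t in enumerate(data.imp_th):
        temph[:, t] = x[:, k + i]
    k += len(data.imp_th)
    for i, t in enumerate(data.imp_rf):
        rainf[:, t] = x[:, k + i]

    lg = special.logit
    inv = special.expit
    out = {
        "pB_Y": inv(lg(x[:, [_mcmc.I_PBY]]) + blk("eps_pB")),
        "pB_A": inv(lg(x[:, [_mcmc.I_PBA]]) + blk("eps_pB")),
        "CS_Y": np.exp(np.log(x[:, [_mcmc.I_CSY]]) + blk("eps_CS")),
        "CS_A": np.exp(np.log(x[:, [_mcmc.I_CSA]]) + blk("eps_CS")),
        "pNS": inv(lg(x[:, [_mcmc.I_PNS]]) + x[:, [_mcmc.I_BR_PNS]] * rainh
                   + x[:, [_mcmc.I_BT_PNS]] * temph + blk("eps_pNS")),
        "sN_Y": inv(lg(x[:, [_mcmc.I_SNY]]) + x[:, [_mcmc.I_BR_SN]] * rainh
                    + x[:, [_mcmc.I_BT_SN]] * temph + blk("eps_sN")),
        "sN_A": inv(lg(x[:, [_mcmc.I_SNA]]) + x[:, [_mcmc.I_BR_SN]] * rainh
                    + x[:, [_mcmc.I_BT_SN]] * temph + blk("eps_sN")),
        "sJ": inv(lg(x[:, [_mcmc.I_SJ]]) + x[:, [_mcmc.I_BR_SJ]] * rainf
                  + blk("eps_sJ")),
        "sA": inv(lg(x[:, [_mcmc.I_SA]]) + blk("eps_sA")),
        "NY": blk("NY"), "NA": blk("NA"), "IY": blk("IY"), "IA": blk("IA"),
        "Om": blk("Om"), "q": x[:, _mcmc.I_Q],
    }
    return out


def theta_draws_from_samples(samples: PosteriorSamples,
                             data: IPMData) -> np.ndarray:
    """Per-draw realized theta series (D, T-1, 12) for posterior LTREs.

    Vital rates come from each draw's link models; immigration rates are the
    draw's realized per-capita rates (latent immigrant counts over previous
    total abundance) and structure is the draw's latent age distribution.
    """
    r = rates_from_draws(samples, data)
    ntot = r["NY"] + r["NA"]
    prev = np.maximum(ntot[:, :-1], 1e-12)
    om_y = r["IY"][:, 1:] / prev
    om_a = r["IA"][:, 1:] / prev
    n_y = r["NY"][:, :-1] / prev
    theta = np.stack([
        r["pB_Y"][:, :-1], r["pB_A"][:, :-1],
        r["CS_Y"][:, :-1], r["CS_A"][:, :-1],
        r["pNS"][:, :-1], r["sN_Y"][:, :-1], r["sN_A"][:, :-1],
        r["sJ"][:, :-1], r["sA"][:, :-1],
        om_y, om_a, np.clip(n_y, 0.0, 1.0),
    ], axis=-1)
    return theta


_STREAMS = ("first_clutches", "eggs", "fledglings", "newly_ringed_adults")


def posterior_predictive_table(samples: PosteriorSamples, data: IPMData,
                               seed: int = 0) -> pd.DataFrame:
    """Predicted versus observed annual counts per stream.

    For each count stream and year: the posterior median and central 95%
    interval of the Poisson posterior-predictive distribution, the observed
    value, and a coverage flag; plus one summary row per stream with the
    empirical coverage over non-missing years.
    """
    r = rates_from_draws(samples, data)
    rng = np.random.default_rng(seed)
    mu = {
        "first_clutches": r["NY"] * r["pB_Y"] + r["NA"] * r["pB_A"],
        "eggs": r["NY"] * r["pB_Y"] * r["CS_Y"]
        + r["NA"] * r["pB_A"] * r["CS_A"],
        "fledglings": r["NY"] * r["pB_Y"] * r["CS_Y"] * r["pNS"] * r["sN_Y"]
        + r["NA"] * r["pB_A"] * r["CS_A"] * r["pNS"] * r["sN_A"],
        "newly_ringed_adults": data.pcap[None, :] * r["Om"],
    }
    obs = {
        "first_clutches": data.firstcl, "eggs": data.eggs,
        "fledglings": data.fled, "newly_ringed_adults": data.newr,
    }
    rows = []
    for stream in _STREAMS:
        sim = rng.poisson(np.maximum(mu[stream], 0.0))
        lo = np.quantile(sim, 0.025, axis=0)
        hi = np.quantile(sim, 0.975, axis=0)
        med = np.quantile(sim, 0.5, axis=0)
        t0 = 1 if stream == "newly_ringed_adults" else 0
        n_cov = 0
        n_obs = 0
        for t in range(t0, samples.T):
            o = obs[stream][t]
            covered = bool(lo[t] <= o <= hi[t]) if not np.isnan(o) else np.nan
            if not np.isnan(o):
                n_obs += 1
                n_cov += int(covered)
            rows.append((stream, int(samples.years[t]), o, med[t],
                         lo[t], hi[t], covered))
        rows.append((stream, -1, np.nan, np.nan, np.nan, np.nan,
                     n_cov / n_obs if n_obs else np.nan))
    return pd.DataFrame(rows, columns=["stream", "year", "observed",
                                       "pred_median", "lower95", "upper95",
                                       "covered"])


def forward_projection_check(samples: PosteriorSamples, data: IPMData,
                             horizon: int, reps: int = 1000,
                             seed: int = 0) -> pd.DataFrame:
    """Stochastic forward projection from posterior medians.

    Time-averaged posterior-median vital rates and expected immigrant
    totals drive :func:`nestipm.core.stochastic_project` from the
    posterior-median final state; per projection year the 2.5/50/97.5%
    quantiles of total population size are reported.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    r = rates_from_draws(samples, data)

    def med_rate(key):
        return float(np.median(np.median(r[key], axis=0)))

    rates = core.VitalRateSeries(
        pB=np.tile([[med_rate("pB_Y")], [med_rate("pB_A")]], (1, horizon)),
        CS=np.tile([[med_rate("CS_Y")], [med_rate("CS_A")]], (1, horizon)),
        pNS=np.full(horizon, med_rate("pNS")),
        sN=np.tile([[med_rate("sN_Y")], [med_rate("sN_A")]], (1, horizon)),
        sJ=np.full(horizon, med_rate("sJ")),
        sA=np.full(horizon, med_rate("sA")),
    )
    om_med = float(np.median(np.median(r["Om"][:, 1:], axis=0)))
    q_med = float(np.median(r["q"]))
    imm = np.zeros((2, horizon))
    imm[0, 1:] = q_med * om_med
    imm[1, 1:] = (1.0 - q_med) * om_med
    init = (int(np.median(r["NY"][:, -1])), int(np.median(r["NA"][:, -1])))
    ens = core.stochastic_project(rates, imm, init, seed=seed, reps=reps)
    ntot = ens.ntot
    rows = []
    for h in range(horizon):
        rows.append((h, np.quantile(ntot[:, h], 0.025),
                     np.quantile(ntot[:, h], 0.5),
                     np.quantile(ntot[:, h], 0.975)))
    return pd.DataFrame(rows, columns=["year_ahead", "lower95", "median",
                                       "upper95"])
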