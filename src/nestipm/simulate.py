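"""Synthetic data generator for nestbox-population studies.

Simulates a complete study — individual females, nest records, capture
histories, daily weather and the derived annual counts — from a known
parameter set (:class:`TruthSet`), inverting the observation models the
inference machinery assumes. Defaults emulate a mid-sized population of a
small hole-nesting migratory passerine: a single brood of six to seven eggs,
apparent adult survival below one half, low apparent juvenile survival
(death and permanent emigration are confounded), and substantial immigration
sustaining the population.

Covariates in the generating link models are the simulated weather means over
the post-hatching / post-fledging windows, standardized with fixed long-run
constants of the weather process (the analysis re-standardizes empirically;
over a multi-decade study the two agree closely).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from . import io as nio

__all__ = ["TruthSet", "SyntheticDataset", "simulate_weather",
           "simulate_dataset", "planted_scenarios", "SCENARIOS"]


def _logit(p):
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return np.log(p) - np.log1p(-p)


@dataclass
class TruthSet:
    """Generating parameters for one synthetic study population.

    Intercepts are on the natural scale; year random effects act on the link
    scale (logit for probabilities, log for clutch size) with the given SDs.
    ``omega_rate`` is the expected per-capita total immigration (immigrants
    entering before next spring's census per female alive this spring), split
    ``q_imm : 1 - q_imm`` between yearlings and adults.
    """

    n_years: int = 40
    n_boxes: int = 150
    init_NY: int = 50
    init_NA: int = 100
    # breeding probability (no covariates)
    pB_Y: float = 0.65
    pB_A: float = 0.90
    sigma_pB: float = 0.20
    # clutch size (log link, no covariates)
    CS_Y: float = 6.0
    CS_A: float = 6.5
    sigma_CS: float = 0.05
    # nest success (post-hatch rain and temperature)
    pNS: float = 0.85
    beta_rain_pNS: float = -0.30
    beta_temp_pNS: float = 0.20
    sigma_pNS: float = 0.30
    # per-egg survival to fledging (post-hatch rain and temperature)
    sN_Y: float = 0.85
    sN_A: float = 0.90
    beta_rain_sN: float = -0.30
    beta_temp_sN: float = 0.10
    sigma_sN: float = 0.30
    # apparent juvenile survival (post-fledging rain)
    sJ: float = 0.10
    beta_rain_sJ: float = -0.30
    sigma_sJ: float = 0.30
    # apparent yearling/adult survival (no covariates)
    sA: float = 0.45
    sigma_sA: float = 0.20
    # immigration
    omega_rate: float = 0.35
    sigma_omega: float = 0.30
    q_imm: float = 0.15
    # observation process
    pCapB_mean: float = 0.85
    pCapB_conc: float = 20.0     # Beta concentration of yearly pCapB
    ring_nestling_prob: float = 0.95
    # phenology
    laying_mean_doy: float = 135.0
    laying_sd_doy: float = 5.0
    start_year: int = 1980
    # long-run standardization constants of the simulated weather process
    rain_hatch_mean: float = 1.89
    rain_hatch_sd: float = 0.88
    temp_hatch_mean: float = 9.63
    temp_hatch_sd: float = 0.81
    rain_fledge_mean: float = 1.81
    rain_fledge_sd: float = 1.28

    def validate(self) -> None:
        probs = ["pB_Y", "pB_A", "pNS", "sN_Y", "sN_A", "sJ", "sA",
                 "q_imm", "pCapB_mean", "ring_nestling_prob"]
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ["sigma_pB", "sigma_CS", "sigma_pNS", "sigma_sN",
                     "sigma_sJ", "sigma_sA", "sigma_omega", "omega_rate",
                     "CS_Y", "CS_A"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_years < 2 or self.n_boxes < 1:
            raise ValueError("need at least 2 years and 1 nestbox")


def simulate_weather(years, seed: int, start_year: int = 1980) -> nio.EnvSeries:
    """Daily May–August minimum temperature and precipitation.

    Temperature follows a seasonal sinusoid plus AR(1) noise; precipitation is
    Bernoulli–Gamma (wet days with Gamma-distributed totals). Reproducible by
    seed; precipitation is non-negative everywhere.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for y in range(start_year, start_year + years):
        dates = pd.date_range(f"{y}-05-01", f"{y}-08-31", freq="D")
        doy = dates.dayofyear.to_numpy()
        seasonal = 4.0 + 6.0 * np.sin(np.pi * (doy - 90) / 160.0)
        ar = np.empty(len(doy))
        ar[0] = rng.normal(0.0, 1.8)
        for i in range(1, len(doy)):
            ar[i] = 0.6 * ar[i - 1] + rng.normal(0.0, 1.8 * np.sqrt(1 - 0.36))
        tmin = seasonal + ar
        wet = rng.random(len(doy)) < 0.4
        amount = rng.gamma(1.2, 4.0, size=len(doy))
        rain = np.where(wet, amount, 0.0)
        frames.append(pd.DataFrame(
            {"date": dates, "tmin_c": np.round(tmin, 2),
             "rain_mm": np.round(rain, 2)}))
    df = pd.concat(frames, ignore_index=True).set_index("date")
    return nio.EnvSeries(frame=df)


#: named scenarios in which one demographic pathway carries the
#: among-year variance (for LTRE power checks)
SCENARIOS = ("baseline", "survival-driven", "immigration-driven",
             "reproduction-driven", "rain-sensitive")


def planted_scenarios(name: str) -> TruthSet:
    """A :class:`TruthSet` in which one pathway carries the among-year variance."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose one of: {', '.join(SCENARIOS)}")
    quiet = dict(sigma_pB=0.0, sigma_CS=0.0, sigma_pNS=0.0, sigma_sN=0.0,
                 sigma_sJ=0.0, sigma_sA=0.0, sigma_omega=0.0,
                 beta_rain_pNS=0.0, beta_temp_pNS=0.0, beta_rain_sN=0.0,
                 beta_temp_sN=0.0, beta_rain_sJ=0.0)
    if name == "baseline":
        truth = TruthSet()
    elif name == "survival-driven":
        truth = TruthSet(**{**quiet, "sigma_sA": 0.40, "sigma_sJ": 0.50})
    elif name == "immigration-driven":
        truth = TruthSet(**{**quiet, "sigma_omega": 0.60})
    elif name == "reproduction-driven":
        truth = TruthSet(**{**quiet, "sigma_pNS": 0.45, "sigma_sN": 0.45,
                            "sigma_pB": 0.35, "sigma_CS": 0.08})
    else:  # rain-sensitive
        truth = TruthSet(beta_rain_pNS=-0.6, beta_rain_sN=-0.6,
                         beta_rain_sJ=-0.6, sigma_pNS=0.15, sigma_sN=0.15,
                         sigma_sJ=0.15, sigma_sA=0.1, sigma_omega=0.1)
    truth.validate()
    return truth


@dataclass
class SyntheticDataset:
    """One simulated study: observation tables plus the generating truth."""

    nests: pd.DataFrame
    captures: pd.DataFrame        # long format sighting rows
    weather: pd.DataFrame         # date-indexed tmin_c / rain_mm
    truth: dict                   # JSON-serializable truth manifest

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.truth["years"])

    def truth_theta_series(self) -> np.ndarray:
        """Generating theta series (T-1, 12) for fit-free LTRE checks.

        Rates are the truth's year-specific values; immigration components
        are the expected per-capita rates; structure is the realized age
        distribution.
        """
        tr = self.truth
        T = len(tr["years"])
        N = np.asarray(tr["N"], dtype=float)
        ntot = N.sum(axis=0)
        om = np.asarray(tr["omega_tot"], dtype=float)
        q = tr["params"]["q_imm"]
        cols = []
        for t in range(T - 1):
            rates = tr["rates"]
            cols.append([
                rates["pB"][0][t], rates["pB"][1][t],
                rates["CS"][0][t], rates["CS"][1][t],
                rates["pNS"][t],
                rates["sN"][0][t], rates["sN"][1][t],
                rates["sJ"][t], rates["sA"][t],
                q * om[t], (1.0 - q) * om[t],
                N[0, t] / ntot[t] if ntot[t] > 0 else 0.0,
            ])
        return np.asarray(cols)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_nest_table(self.nests, out / "nests.csv")
        self.captures.to_csv(out / "captures.csv", index=False)
        self.weather.reset_index().to_csv(out / "weather.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _year_rates(truth: TruthSet, eps: dict, covs: dict, t: int) -> dict:
    """Natural-scale rates for year t given year effects and covariates."""
    inv = special.expit
    rh, th, rf = covs["rain_hatch"][t], covs["temp_hatch"][t], covs["rain_fledge"][t]
    return {
        "pB_Y": inv(_logit(truth.pB_Y) + eps["pB"][t]),
        "pB_A": inv(_logit(truth.pB_A) + eps["pB"][t]),
        "CS_Y": np.exp(np.log(truth.CS_Y) + eps["CS"][t]),
        "CS_A": np.exp(np.log(truth.CS_A) + eps["CS"][t]),
        "pNS": inv(_logit(truth.pNS) + truth.beta_rain_pNS * rh
                   + truth.beta_temp_pNS * th + eps["pNS"][t]),
        "sN_Y": inv(_logit(truth.sN_Y) + truth.beta_rain_sN * rh
                    + truth.beta_temp_sN * th + eps["sN"][t]),
        "sN_A": inv(_logit(truth.sN_A) + truth.beta_rain_sN * rh
                    + truth.beta_temp_sN * th + eps["sN"][t]),
        "sJ": inv(_logit(truth.sJ) + truth.beta_rain_sJ * rf + eps["sJ"][t]),
        "sA": inv(_logit(truth.sA) + eps["sA"][t]),
    }


def simulate_dataset(truth: TruthSet, seed: int,
                     out_dir=None) -> SyntheticDataset:
    """Simulate a full study from known parameters.

    Individual females are tracked through breeding, ringing, survival and
    recapture, so the emitted nest records, capture histories and weather
    reproduce exactly the CSV dialects the readers expect. If the population
    goes extinct before half the requested years, a warning is issued and the
    dataset is truncated at the extinction year.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    T = truth.n_years
    env = simulate_weather(T, int(rng.integers(2**31)), truth.start_year)

    eps = {k: rng.normal(0.0, getattr(truth, "sigma_" + k), size=T)
           for k in ("pB", "CS", "pNS", "sN", "sJ", "sA")}
    omega_tot = truth.omega_rate * np.exp(
        rng.normal(0.0, truth.sigma_omega, size=T)
        - 0.5 * truth.sigma_omega**2)
    if truth.pCapB_mean >= 1.0:
        pcap = np.ones(T)
    elif truth.pCapB_mean <= 0.0:
        pcap = np.zeros(T)
    else:
        pcap = rng.beta(truth.pCapB_mean * truth.pCapB_conc,
                        (1 - truth.pCapB_mean) * truth.pCapB_conc, size=T)

    # individual bookkeeping: ids of living females by age class
    next_id = [0]

    def new_females(n, prefix):
        ids = [f"{prefix}{next_id[0] + i:06d}" for i in range(n)]
        next_id[0] += n
        return ids

    ring_info: dict[str, tuple[str, int]] = {}   # id -> (ring_age, first year idx)
    sightings: list[tuple[str, int]] = []        # (id, year idx) resightings
    yearlings: list[dict] = []
    adults: list[dict] = []
    for i in new_females(truth.init_NY, "I"):
        yearlings.append({"id": i, "ringed": False})
    for i in new_females(truth.init_NA, "I"):
        adults.append({"id": i, "ringed": False})

    nest_rows = []
    N = np.zeros((2, T), dtype=int)
    imm = np.zeros((2, T), dtype=int)
    rates_store = {"pB": np.zeros((2, T)), "CS": np.zeros((2, T)),
                   "pNS": np.zeros(T), "sN": np.zeros((2, T)),
                   "sJ": np.zeros(T), "sA": np.zeros(T)}
    covs = {"rain_hatch": np.zeros(T), "temp_hatch": np.zeros(T),
            "rain_fledge": np.zeros(T)}
    t_end = T

    for t in range(T):
        year = truth.start_year + t
        N[0, t] = len(yearlings)
        N[1, t] = len(adults)
        ntot = N[:, t].sum()
        if ntot == 0:
            t_end = t
            break

        # breeding decisions need pB before weather covariates are known;
        # pB carries no covariates so this ordering is consistent
        pB_Y = special.expit(_logit(truth.pB_Y) + eps["pB"][t])
        pB_A = special.expit(_logit(truth.pB_A) + eps["pB"][t])
        CS_Y = np.exp(np.log(truth.CS_Y) + eps["CS"][t])
        CS_A = np.exp(np.log(truth.CS_A) + eps["CS"][t])

        nests_t = []
        for females, pB, CS, age_name in ((yearlings, pB_Y, CS_Y, "yearling"),
                                          (adults, pB_A, CS_A, "adult")):
            for f in females:
                if rng.random() >= pB:
                    continue
                clutch = 0
                while clutch < 1:
                    clutch = rng.poisson(CS)
                fe = int(round(rng.normal(truth.laying_mean_doy,
                                          truth.laying_sd_doy)))
                nests_t.append({"female": f, "age": age_name,
                                "first_egg": fe, "clutch": clutch})

        # covariate windows from this year's hatch dates
        if nests_t:
            hatch = [n["first_egg"] + n["clutch"] + nio.INCUBATION_DAYS
                     for n in nests_t]
            w_hatch = nio.posthatch_window(hatch)
            w_fledge = nio.postfledge_window(hatch)
            rh_raw, _ = nio.aggregate_covariate(env, year, w_hatch, "rain_mm")
            th_raw, _ = nio.aggregate_covariate(env, year, w_hatch, "tmin_c")
            rf_raw, _ = nio.aggregate_covariate(env, year, w_fledge, "rain_mm")
        else:
            rh_raw = th_raw = rf_raw = np.nan
        covs["rain_hatch"][t] = (rh_raw - truth.rain_hatch_mean) / truth.rain_hatch_sd \
            if not np.isnan(rh_raw) else 0.0
        covs["temp_hatch"][t] = (th_raw - truth.temp_hatch_mean) / truth.temp_hatch_sd \
            if not np.isnan(th_raw) else 0.0
        covs["rain_fledge"][t] = (rf_raw - truth.rain_fledge_mean) / truth.rain_fledge_sd \
            if not np.isnan(rf_raw) else 0.0

        r = _year_rates(truth, eps, covs, t)
        rates_store["pB"][:, t] = (r["pB_Y"], r["pB_A"])
        rates_store["CS"][:, t] = (r["CS_Y"], r["CS_A"])
        rates_store["pNS"][t] = r["pNS"]
        rates_store["sN"][:, t] = (r["sN_Y"], r["sN_A"])
        rates_store["sJ"][t] = r["sJ"]
        rates_store["sA"][t] = r["sA"]

        # nest fates, identification and nestling ringing
        new_recruits_pool = []   # (ringed?, id or None) per female fledgling
        for n in nests_t:
            sn = r["sN_Y"] if n["age"] == "yearling" else r["sN_A"]
            if rng.random() >= r["pNS"]:
                fledged = 0
            else:
                fledged = int(rng.binomial(n["clutch"], sn))
            female = n["female"]
            identified = rng.random() < pcap[t]
            if identified:
                if not female["ringed"]:
                    female["ringed"] = True
                    ring_info[female["id"]] = ("adult", t)
                else:
                    sightings.append((female["id"], t))
            fem_fledged = int(rng.binomial(fledged, 0.5))
            for _ in range(fem_fledged):
                if rng.random() < truth.ring_nestling_prob:
                    (nid,) = new_females(1, "N")
                    ring_info[nid] = ("nestling", t)
                    new_recruits_pool.append((True, nid))
                else:
                    new_recruits_pool.append((False, None))
            nest_rows.append({
                "site": "SYN", "year": year, "box": len(nest_rows) % truth.n_boxes,
                "first_egg_doy": n["first_egg"], "clutch": n["clutch"],
                "fledged": fledged,
                "female_id": female["id"] if identified else "",
                "female_age": n["age"], "replacement": False,
            })

        if t == T - 1:
            break
        # survival to next spring
        survivors = [f for f in yearlings + adults
                     if rng.random() < r["sA"]]
        recruits = []
        for ringed, rid in new_recruits_pool:
            if rng.random() < r["sJ"]:
                if ringed:
                    recruits.append({"id": rid, "ringed": True})
                else:
                    (uid,) = new_females(1, "U")
                    recruits.append({"id": uid, "ringed": False})
        mu = omega_tot[t] * ntot
        n_iy = rng.poisson(truth.q_imm * mu)
        n_ia = rng.poisson((1.0 - truth.q_imm) * mu)
        imm[0, t + 1] = n_iy
        imm[1, t + 1] = n_ia
        yearlings = recruits + [{"id": i, "ringed": False}
                                for i in new_females(n_iy, "I")]
        adults = survivors + [{"id": i, "ringed": False}
                              for i in new_females(n_ia, "I")]

    if t_end < (T + 1) // 2:
        warnings.warn(f"population extinct after {t_end} of {T} requested "
                      "years; dataset truncated")
    T = t_end if t_end < T else T

    years = np.arange(truth.start_year, truth.start_year + T)
    nests = pd.DataFrame(nest_rows, columns=nio.NEST_COLUMNS)
    nests = nests[nests["year"] < truth.start_year + T]
    nests["female_id"] = nests["female_id"].replace("", np.nan)

    cap_rows = []
    for ind, (ring_age, fy) in ring_info.items():
        if fy >= T:
            continue
        cap_rows.append({"individual": ind, "ring_age": ring_age,
                         "first_year": int(years[fy]),
                         "year_seen": int(years[fy])})
    for ind, t in sightings:
        if t < T:
            cap_rows.append({"individual": ind,
                             "ring_age": ring_info[ind][0],
                             "first_year": int(years[ring_info[ind][1]]),
                             "year_seen": int(years[t])})
    captures = pd.DataFrame(cap_rows, columns=nio.CAPTURE_COLUMNS)
    captures = captures.sort_values(["individual", "year_seen"],
                                    kind="stable").reset_index(drop=True)

    manifest = {
        "params": asdict(truth),
        "years": [int(y) for y in years],
        "N": N[:, :T].tolist(),
        "imm": imm[:, :T].tolist(),
        "omega_tot": omega_tot[:T].tolist(),
        "pCapB": pcap[:T].tolist(),
        "rates": {
            "pB": rates_store["pB"][:, :T].tolist(),
            "CS": rates_store["CS"][:, :T].tolist(),
            "pNS": rates_store["pNS"][:T].tolist(),
            "sN": rates_store["sN"][:, :T].tolist(),
            "sJ": rates_store["sJ"][:T].tolist(),
            "sA": rates_store["sA"][:T].tolist(),
        },
        "covariates": {k: v[:T].tolist() for k, v in covs.items()},
    }
    ds = SyntheticDataset(nests=nests, captures=captures,
                          weather=env.frame, truth=manifest)
    if out_dir is not None:
        ds.write(out_dir)
    return ds
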