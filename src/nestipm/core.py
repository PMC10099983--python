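"""Age-structured demographic core for a female-based, two-age-class population.

The population is censused pre-breeding, so the youngest countable class is
yearlings (age 1). Dynamics from spring of year t to spring of year t+1:

    N_Y[t+1] = 0.5 * F_Y[t] * sJ[t] * N_Y[t] + 0.5 * F_A[t] * sJ[t] * N_A[t] + ImmY[t+1]
    N_A[t+1] = sA[t] * (N_Y[t] + N_A[t]) + ImmA[t+1]

where the age-specific fecundity F_a = pB_a * CS_a * pNS * sN_a is the expected
number of fledglings per female (breeding probability x clutch size x nest
success x per-egg survival to fledging), 0.5 is the female share of fledglings,
sJ is apparent first-year survival, sA apparent yearling/adult survival, and
ImmY/ImmA are immigrant females entering before the census.

The module also provides realized growth rates, the additive decomposition of
the annual growth rate lambda into vital-rate and immigration components, a
stochastic projection kernel with demographic (Binomial/Poisson) noise, and
post-hoc summaries used for multi-population comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AGE_YEARLING",
    "AGE_ADULT",
    "AGE_NAMES",
    "THETA_NAMES",
    "ThetaVector",
    "VitalRateSeries",
    "ImmigrationSeries",
    "PopulationState",
    "ProjectionEnsemble",
    "fecundity",
    "project_expectation",
    "realized_growth",
    "lambda_decomposed",
    "breeding_population",
    "stochastic_project",
    "realized_theta",
    "growth_covariation",
    "population_trend",
]

AGE_YEARLING = 0
AGE_ADULT = 1
AGE_NAMES = ("yearling", "adult")

#: Fixed parameter ordering shared by the LTRE sensitivity machinery.
THETA_NAMES = (
    "pB_Y", "pB_A", "CS_Y", "CS_A", "pNS", "sN_Y", "sN_A",
    "sJ", "sA", "omega_Y", "omega_A", "n_Y",
)

_PROB_COMPONENTS = {"pB_Y", "pB_A", "pNS", "sN_Y", "sN_A", "sJ", "sA"}


def _check_prob(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"{name} must lie in [0, 1], got value(s) outside bounds")


def _check_nonneg(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ThetaVector:
    """One year's vital rates, immigration rates and population structure.

    ``n_A`` is implied as ``1 - n_Y``. The component ordering used when
    converting to/from arrays is :data:`THETA_NAMES` and is shared with the
    LTRE sensitivity vector.
    """

    pB_Y: float
    pB_A: float
    CS_Y: float
    CS_A: float
    pNS: float
    sN_Y: float
    sN_A: float
    sJ: float
    sA: float
    omega_Y: float = 0.0
    omega_A: float = 0.0
    n_Y: float = 0.5

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in THETA_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ThetaVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(THETA_NAMES),):
            raise ValueError(f"expected a length-{len(THETA_NAMES)} vector")
        return cls(**dict(zip(THETA_NAMES, arr)))

    def validate(self, cs_max: float = 20.0) -> None:
        for name in _PROB_COMPONENTS:
            _check_prob(name, getattr(self, name))
        for name in ("CS_Y", "CS_A", "omega_Y", "omega_A"):
            _check_nonneg(name, getattr(self, name))
        if self.CS_Y > cs_max or self.CS_A > cs_max:
            raise ValueError(f"clutch size exceeds configured upper bound {cs_max}")
        if not 0.0 <= self.n_Y <= 1.0:
            raise ValueError("n_Y must lie in [0, 1]")


@dataclass
class VitalRateSeries:
    """Age- and year-indexed vital rates.

    Arrays with an age axis have shape ``(2, T)`` with row 0 = yearling
    mothers, row 1 = adult mothers; year-only arrays have shape ``(T,)``.
    """

    pB: np.ndarray   # breeding probability, (2, T)
    CS: np.ndarray   # expected clutch size (eggs), (2, T)
    pNS: np.ndarray  # nest success probability (no complete failure), (T,)
    sN: np.ndarray   # per-egg survival to fledging given success, (2, T)
    sJ: np.ndarray   # apparent survival fledging -> age 1, (T,)
    sA: np.ndarray   # apparent annual survival of yearlings/adults, (T,)
    cs_max: float = 20.0

    def __post_init__(self) -> None:
        self.pB = np.atleast_2d(np.asarray(self.pB, dtype=float))
        self.CS = np.atleast_2d(np.asarray(self.CS, dtype=float))
        self.sN = np.atleast_2d(np.asarray(self.sN, dtype=float))
        self.pNS = np.asarray(self.pNS, dtype=float)
        self.sJ = np.asarray(self.sJ, dtype=float)
        self.sA = np.asarray(self.sA, dtype=float)
        T = self.pB.shape[1]
        for name in ("pB", "CS", "sN"):
            if getattr(self, name).shape != (2, T):
                raise ValueError(f"{name} must have shape (2, T)")
        for name in ("pNS", "sJ", "sA"):
            if getattr(self, name).shape != (T,):
                raise ValueError(f"{name} must have shape (T,) matching the year axis")
        for name in ("pB", "pNS", "sN", "sJ", "sA"):
            _check_prob(name, getattr(self, name))
        _check_nonneg("CS", self.CS)
        if np.any(self.CS > self.cs_max):
            raise ValueError(f"CS exceeds configured upper bound {self.cs_max}")

    @property
    def n_years(self) -> int:
        return self.pB.shape[1]

    def fecundity(self) -> np.ndarray:
        """Expected fledglings per female by age class, shape (2, T)."""
        return fecundity(self.pB, self.CS, self.pNS[None, :], self.sN,
                         cs_max=self.cs_max)


@dataclass
class ImmigrationSeries:
    """Immigrant female counts by age and the derived per-capita rates.

    ``imm_count[a, t]`` immigrants enter before the census of year t
    (``imm_count[:, 0]`` is zero by convention: the initial census has no
    separately identified immigrants). The per-capita rate is defined against
    the previous year's total: ``omega[a, t] = imm_count[a, t + 1] / Ntot[t]``.
    """

    imm_count: np.ndarray  # (2, T) integers

    def __post_init__(self) -> None:
        self.imm_count = np.atleast_2d(np.asarray(self.imm_count))
        if np.any(self.imm_count < 0):
            raise ValueError("immigrant counts must be non-negative")
        if np.any(self.imm_count != np.round(self.imm_count)):
            raise ValueError("immigrant counts must be integers")

    def omega(self, ntot: np.ndarray) -> np.ndarray:
        """Per-capita immigration rates, shape (2, T-1); NaN where Ntot=0."""
        ntot = np.asarray(ntot, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            om = self.imm_count[:, 1:] / ntot[None, :-1]
        return np.where(ntot[None, :-1] > 0, om, np.nan)


@dataclass
class PopulationState:
    """Latent female abundances at the pre-breeding census, shape (2, T)."""

    N: np.ndarray

    def __post_init__(self) -> None:
        self.N = np.atleast_2d(np.asarray(self.N))
        if np.any(self.N < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def ntot(self) -> np.ndarray:
        return self.N.sum(axis=0)

    @property
    def structure(self) -> np.ndarray:
        """Age proportions n[a, t]; NaN in years with Ntot = 0."""
        ntot = self.ntot.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            n = self.N / ntot[None, :]
        return np.where(ntot[None, :] > 0, n, np.nan)


def fecundity(pB, CS, pNS, sN, *, cs_max: float = 20.0):
    """Expected fledglings per female: ``pB * CS * pNS * sN``.

    All arguments broadcast; probabilities are validated against [0, 1] and
    clutch size against [0, cs_max].
    """
    _check_prob("pB", pB)
    _check_prob("pNS", pNS)
    _check_prob("sN", sN)
    _check_nonneg("CS", CS)
    if np.any(np.asarray(CS, dtype=float) > cs_max):
        raise ValueError(f"CS exceeds configured upper bound {cs_max}")
    return np.asarray(pB, float) * np.asarray(CS, float) \
        * np.asarray(pNS, float) * np.asarray(sN, float)


def project_expectation(n_yearling, n_adult, theta: ThetaVector, imm_next=(0.0, 0.0)):
    """Expected next-year abundances under the deterministic projection.

    Returns ``(N_Y', N_A')`` where recruits are 0.5*F_a*sJ per female of age a
    and survivors are sA per female of either age, plus the immigrant counts
    entering before next year's census.
    """
    n_yearling = np.asarray(n_yearling, dtype=float)
    n_adult = np.asarray(n_adult, dtype=float)
    _check_nonneg("N_Y", n_yearling)
    _check_nonneg("N_A", n_adult)
    imm_y, imm_a = imm_next
    if np.any(np.asarray(imm_y, float) < 0) or np.any(np.asarray(imm_a, float) < 0):
        raise ValueError("immigrant counts must be non-negative")
    f_y = fecundity(theta.pB_Y, theta.CS_Y, theta.pNS, theta.sN_Y)
    f_a = fecundity(theta.pB_A, theta.CS_A, theta.pNS, theta.sN_A)
    _check_prob("sJ", theta.sJ)
    _check_prob("sA", theta.sA)
    ny_next = 0.5 * f_y * theta.sJ * n_yearling + 0.5 * f_a * theta.sJ * n_adult + imm_y
    na_next = theta.sA * (n_yearling + n_adult) + imm_a
    return ny_next, na_next


def realized_growth(ntot) -> np.ndarray:
    """Realized annual growth rates lambda[t] = Ntot[t+1] / Ntot[t].

    Years with a zero denominator yield NaN (flagged missing) rather than an
    exception, so batch runs survive local extinctions.
    """
    ntot = np.asarray(ntot, dtype=float)
    if ntot.ndim != 1 or ntot.size < 2:
        raise ValueError("need a 1-d series of at least two years")
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = ntot[1:] / ntot[:-1]
    return np.where(ntot[:-1] > 0, lam, np.nan)


def lambda_decomposed(theta) -> np.ndarray:
    """Annual growth rate from the additive vital-rate decomposition.

        lambda = n_Y*0.5*F_Y*sJ + (1 - n_Y)*0.5*F_A*sJ + sA + omega_Y + omega_A

    ``theta`` may be a :class:`ThetaVector` or an array whose last axis has
    length 12 ordered as :data:`THETA_NAMES`. When each component is set to its
    realized per-capita value from a simulated trajectory (see
    :func:`realized_theta`), this reproduces :func:`realized_growth` exactly.
    """
    if isinstance(theta, ThetaVector):
        arr = theta.to_array()
    else:
        arr = np.asarray(theta, dtype=float)
    if arr.shape[-1] != len(THETA_NAMES):
        raise ValueError("theta must have 12 components on its last axis")
    n_y = arr[..., 11]
    if np.any(n_y < 0) or np.any(n_y > 1):
        raise ValueError("n_Y must lie in [0, 1]")
    f_y = arr[..., 0] * arr[..., 2] * arr[..., 4] * arr[..., 5]
    f_a = arr[..., 1] * arr[..., 3] * arr[..., 4] * arr[..., 6]
    lam = (n_y * 0.5 * f_y * arr[..., 7]
           + (1.0 - n_y) * 0.5 * f_a * arr[..., 7]
           + arr[..., 8] + arr[..., 9] + arr[..., 10])
    return lam if lam.shape else float(lam)


def breeding_population(N, pB):
    """Expected breeders B = sum_a N[a]*pB[a] and breeding fraction B/Ntot.

    The fraction is NaN (flagged missing) when Ntot is zero.
    """
    N = np.asarray(N, dtype=float)
    pB = np.asarray(pB, dtype=float)
    _check_nonneg("N", N)
    _check_prob("pB", pB)
    breeders = (N * pB).sum(axis=0)
    ntot = N.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = breeders / ntot
    frac = np.where(ntot > 0, frac, np.nan)
    return breeders, frac


@dataclass
class ProjectionEnsemble:
    """Bookkeeping arrays from :func:`stochastic_project`.

    All arrays have a leading replicate axis; age-structured arrays have shape
    ``(reps, 2, T)``; ``recruits``/``survivors`` record arrivals *into* year t
    (zero at t=0).
    """

    N: np.ndarray           # (reps, 2, T) abundances at census
    breeders: np.ndarray    # (reps, 2, T)
    eggs: np.ndarray        # (reps, 2, T)
    eggs_ok: np.ndarray     # (reps, 2, T) eggs surviving complete-failure stage
    fledged: np.ndarray     # (reps, 2, T)
    fem_fledged: np.ndarray  # (reps, T) female fledglings (all mothers)
    recruits: np.ndarray    # (reps, T) local recruits arriving at census t
    survivors: np.ndarray   # (reps, T) adult survivors arriving at census t
    imm: np.ndarray         # (reps, 2, T) immigrants arriving at census t

    @property
    def ntot(self) -> np.ndarray:
        return self.N.sum(axis=1)


def stochastic_project(rates: VitalRateSeries, imm_expected, init, *,
                       seed: int, reps: int = 1) -> ProjectionEnsemble:
    """Stochastic forward projection with demographic noise.

    Kernel chain per year and age class: breeders ~ Binomial(N, pB); eggs ~
    Poisson(breeders * CS); eggs surviving complete nest failure ~
    Binomial(eggs, pNS); fledglings ~ Binomial(surviving eggs, sN); female
    fledglings ~ Binomial(fledged, 0.5); recruits ~ Binomial(females, sJ);
    adult survivors ~ Binomial(Ntot, sA); immigrants ~ Poisson(expected).
    Extinct trajectories remain at zero. Reproducible under a fixed seed.

    Parameters
    ----------
    imm_expected : array (2, T)
        Expected immigrant counts entering before the census of each year;
        year 0 is ignored (initial abundances are given by ``init``).
    init : (int, int)
        Initial (N_Y, N_A) at the first census.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    T = rates.n_years
    imm_expected = np.atleast_2d(np.asarray(imm_expected, dtype=float))
    if imm_expected.shape != (2, T):
        raise ValueError("imm_expected must have shape (2, T)")
    _check_nonneg("imm_expected", imm_expected)
    rng = np.random.default_rng(seed)

    shape_a = (reps, 2, T)
    out = ProjectionEnsemble(
        N=np.zeros(shape_a, dtype=np.int64),
        breeders=np.zeros(shape_a, dtype=np.int64),
        eggs=np.zeros(shape_a, dtype=np.int64),
        eggs_ok=np.zeros(shape_a, dtype=np.int64),
        fledged=np.zeros(shape_a, dtype=np.int64),
        fem_fledged=np.zeros((reps, T), dtype=np.int64),
        recruits=np.zeros((reps, T), dtype=np.int64),
        survivors=np.zeros((reps, T), dtype=np.int64),
        imm=np.zeros(shape_a, dtype=np.int64),
    )
    out.N[:, AGE_YEARLING, 0] = int(init[0])
    out.N[:, AGE_ADULT, 0] = int(init[1])

    for t in range(T):
        N_t = out.N[:, :, t]
        breeders = rng.binomial(N_t, rates.pB[None, :, t])
        eggs = rng.poisson(breeders * rates.CS[None, :, t])
        eggs_ok = rng.binomial(eggs, rates.pNS[t])
        fledged = rng.binomial(eggs_ok, rates.sN[None, :, t])
        fem = rng.binomial(fledged.sum(axis=1), 0.5)
        out.breeders[:, :, t] = breeders
        out.eggs[:, :, t] = eggs
        out.eggs_ok[:, :, t] = eggs_ok
        out.fledged[:, :, t] = fledged
        out.fem_fledged[:, t] = fem
        if t == T - 1:
            break
        recruits = rng.binomial(fem, rates.sJ[t])
        survivors = rng.binomial(N_t.sum(axis=1), rates.sA[t])
        imm_y = rng.poisson(imm_expected[AGE_YEARLING, t + 1], size=reps)
        imm_a = rng.poisson(imm_expected[AGE_ADULT, t + 1], size=reps)
        out.recruits[:, t + 1] = recruits
        out.survivors[:, t + 1] = survivors
        out.imm[:, AGE_YEARLING, t + 1] = imm_y
        out.imm[:, AGE_ADULT, t + 1] = imm_a
        out.N[:, AGE_YEARLING, t + 1] = recruits + imm_y
        out.N[:, AGE_ADULT, t + 1] = survivors + imm_a
    return out


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, 0.0)


def realized_theta(ens: ProjectionEnsemble) -> np.ndarray:
    """Realized per-capita theta series from a projection ensemble.

    Returns an array of shape ``(reps, T - 1, 12)`` ordered as
    :data:`THETA_NAMES`. Components are defined so the products telescope to
    the realized counts, making

        lambda_decomposed(realized_theta(ens)) == realized_growth(Ntot)

    exact (up to floating representation of integer ratios):

    * pB_a = breeders_a / N_a and CS_a = eggs_a / breeders_a
    * pNS = (eggs surviving complete failure, both ages) / (all eggs)
    * sN_a = fledged_a / (eggs_a * pNS)
    * sJ = recruits[t+1] / (0.5 * fledged_total[t])  (absorbs the female-share
      draw, so the fixed 0.5 in the decomposition stays exact)
    * sA = survivors[t+1] / Ntot[t]; omega_a = imm_a[t+1] / Ntot[t]
    * n_Y = N_Y[t] / Ntot[t]

    Zero denominators yield zero components (their products are then zero
    counts, so the identity still holds).
    """
    N = ens.N[:, :, :-1].astype(float)
    ntot = N.sum(axis=1)
    breeders = ens.breeders[:, :, :-1].astype(float)
    eggs = ens.eggs[:, :, :-1].astype(float)
    eggs_ok_tot = ens.eggs_ok[:, :, :-1].sum(axis=1).astype(float)
    eggs_tot = eggs.sum(axis=1)
    fledged = ens.fledged[:, :, :-1].astype(float)
    fled_tot = fledged.sum(axis=1)

    pB = _safe_div(breeders, N)
    CS = _safe_div(eggs, breeders)
    pNS = _safe_div(eggs_ok_tot, eggs_tot)
    sN = _safe_div(fledged, eggs * pNS[:, None, :])
    sJ = _safe_div(ens.recruits[:, 1:], 0.5 * fled_tot)
    sA = _safe_div(ens.survivors[:, 1:], ntot)
    om_y = _safe_div(ens.imm[:, AGE_YEARLING, 1:], ntot)
    om_a = _safe_div(ens.imm[:, AGE_ADULT, 1:], ntot)
    n_y = _safe_div(N[:, AGE_YEARLING, :], ntot)

    theta = np.stack([
        pB[:, 0], pB[:, 1], CS[:, 0], CS[:, 1], pNS, sN[:, 0], sN[:, 1],
        sJ, sA, om_y, om_a, n_y,
    ], axis=-1)
    return theta


def growth_covariation(ntot_by_pop: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of year-by-year log changes in Ntot.

    ``ntot_by_pop`` is a year-indexed DataFrame with one column per
    population; missing years are NaN. Correlations use overlapping years only
    (pairwise deletion); cells with fewer than ``min_overlap`` overlapping
    changes are NaN. The diagonal is 1.
    """
    if ntot_by_pop.shape[1] < 2:
        raise ValueError("need at least two populations")
    logs = np.log(ntot_by_pop.where(ntot_by_pop > 0))
    dlog = logs.diff()
    corr = dlog.corr(method="pearson", min_periods=min_overlap)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def population_trend(ntot) -> float:
    """Spearman rank correlation of Ntot against year (trend coefficient).

    Constant series return 0 (mid-rank ties leave no monotone signal).
    """
    ntot = np.asarray(ntot, dtype=float)
    if ntot.size < 3:
        raise ValueError("need at least three years")
    if np.all(ntot == ntot[0]):
        return 0.0
    rho, _ = stats.spearmanr(np.arange(ntot.size), ntot)
    return float(rho)
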