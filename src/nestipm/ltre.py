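"""Transient life table response experiments (LTREs).

Retrospective decompositions of variation and change in realized population
growth rates into contributions from vital rates, immigration rates and
population structure, based on the additive decomposition

    lambda = n_Y*0.5*F_Y*sJ + n_A*0.5*F_A*sJ + sA + omega_Y + omega_A.

Three designs are implemented:

* **random** — contributions of among-year (co)variation in each component to
  var(lambda_t): ``c_i = sum_j cov(theta_i, theta_j) * s_i * s_j`` with
  sensitivities evaluated at the temporal mean;
* **fixed** — contributions of year-to-year changes to the change in annual
  growth rate: ``c_i = (theta_i[t+1] - theta_i[t]) * s_i``;
* **period** — contributions of changes in component means and SDs between
  two equal-length periods to the change in log geometric mean growth, using
  numerically computed real-time elasticities that separate direct effects
  from indirect effects mediated by perturbation of population structure.

All designs can be applied per posterior draw to propagate parameter
uncertainty into the contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import THETA_NAMES, ThetaVector, lambda_decomposed

__all__ = [
    "GROUPS",
    "SensitivityVector",
    "ElasticitySet",
    "LTREContributions",
    "sensitivities",
    "random_design",
    "fixed_design",
    "fixed_design_series",
    "realtime_elasticities",
    "period_design",
    "posterior_ltre",
]

#: Grouping of theta components used in summaries.
GROUPS = {
    "pB_Y": "reproduction", "pB_A": "reproduction",
    "CS_Y": "reproduction", "CS_A": "reproduction",
    "pNS": "reproduction", "sN_Y": "reproduction", "sN_A": "reproduction",
    "sJ": "survival", "sA": "survival",
    "omega_Y": "immigration", "omega_A": "immigration",
    "n_Y": "structure",
}

_PROB_IDX = [0, 1, 4, 5, 6, 7, 8]   # probability-type components
_N_Y_IDX = 11


def _as_theta_array(theta) -> np.ndarray:
    if isinstance(theta, ThetaVector):
        return theta.to_array()
    arr = np.asarray(theta, dtype=float)
    if arr.shape[-1] != len(THETA_NAMES):
        raise ValueError("theta must have 12 components on its last axis")
    return arr


def _validate_theta(arr: np.ndarray) -> None:
    for i in _PROB_IDX:
        if np.any(arr[..., i] < 0) or np.any(arr[..., i] > 1):
            raise ValueError(f"{THETA_NAMES[i]} outside [0, 1]")
    if np.any(arr[..., 2:4] < 0) or np.any(arr[..., 9:11] < 0):
        raise ValueError("clutch sizes and immigration rates must be non-negative")
    if np.any(arr[..., _N_Y_IDX] < 0) or np.any(arr[..., _N_Y_IDX] > 1):
        raise ValueError("n_Y outside [0, 1]")


@dataclass
class SensitivityVector:
    """Partial derivatives of lambda w.r.t. each theta component at theta_bar."""

    values: np.ndarray                       # (12,)
    reference: np.ndarray                    # theta_bar, (12,)
    names: tuple = THETA_NAMES

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class ElasticitySet:
    """Real-time elasticities of geometric mean growth over one period.

    For each perturbable component: the response of log lambda_g to a
    relative perturbation of the component's within-period mean (``mu``) or
    SD (``sigma``), split into the direct part (``_T``, structure frozen at
    the baseline path) and the part mediated by the induced change in
    population structure (``_struct``).
    """

    e_mu_T: dict[str, float]
    e_mu_struct: dict[str, float]
    e_sigma_T: dict[str, float]
    e_sigma_struct: dict[str, float]
    log_lambda_g: float
    period: tuple[int, int]


@dataclass
class LTREContributions:
    """Per-component contributions from one LTRE design.

    ``total`` is the exact sum of the (non-missing) contributions;
    ``reference`` is the quantity the total approximates (var(lambda_t),
    delta lambda_t, or delta log lambda_g). ``components`` (period design
    only) splits each contribution into mu/sigma x direct/indirect parts.
    """

    design: str
    contributions: dict[str, float]
    total: float
    reference: float | None = None
    components: pd.DataFrame | None = None
    groups: dict[str, str] = field(default_factory=lambda: dict(GROUPS))

    def grouped(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for name, value in self.contributions.items():
            g = self.groups[name]
            if not np.isnan(value):
                out[g] = out.get(g, 0.0) + value
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "parameter": list(self.contributions),
            "group": [self.groups[n] for n in self.contributions],
            "contribution": list(self.contributions.values()),
        })
        df["design"] = self.design
        return df


def sensitivities(theta_bar) -> SensitivityVector:
    """Analytic sensitivities of lambda at the reference point theta_bar.

    lambda is affine in sA and the immigration rates, so those sensitivities
    are exactly 1 and independent of population structure.
    """
    arr = _as_theta_array(theta_bar)
    if arr.ndim != 1:
        raise ValueError("theta_bar must be a single theta vector")
    _validate_theta(arr)
    pB_Y, pB_A, CS_Y, CS_A, pNS, sN_Y, sN_A, sJ, sA, om_y, om_a, n_Y = arr
    n_A = 1.0 - n_Y
    F_Y = pB_Y * CS_Y * pNS * sN_Y
    F_A = pB_A * CS_A * pNS * sN_A
    s = np.array([
        0.5 * n_Y * sJ * CS_Y * pNS * sN_Y,              # pB_Y
        0.5 * n_A * sJ * CS_A * pNS * sN_A,              # pB_A
        0.5 * n_Y * sJ * pB_Y * pNS * sN_Y,              # CS_Y
        0.5 * n_A * sJ * pB_A * pNS * sN_A,              # CS_A
        0.5 * sJ * (n_Y * pB_Y * CS_Y * sN_Y
                    + n_A * pB_A * CS_A * sN_A),         # pNS
        0.5 * n_Y * sJ * pB_Y * CS_Y * pNS,              # sN_Y
        0.5 * n_A * sJ * pB_A * CS_A * pNS,              # sN_A
        0.5 * (n_Y * F_Y + n_A * F_A),                   # sJ
        1.0,                                             # sA
        1.0,                                             # omega_Y
        1.0,                                             # omega_A
        0.5 * sJ * (F_Y - F_A),                          # n_Y
    ])
    return SensitivityVector(values=s, reference=arr)


def random_design(theta_series) -> LTREContributions:
    """Contributions of among-year (co)variation to var(lambda_t).

    ``theta_series`` has shape (T, 12); sensitivities are evaluated at the
    component-wise temporal mean, covariances use the sample (n-1) estimator.
    The total equals s' Sigma s exactly and approximates the sample variance
    of lambda_t to first order.
    """
    arr = _as_theta_array(theta_series)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need a (T, 12) series with at least three years")
    theta_bar = arr.mean(axis=0)
    s = sensitivities(theta_bar).values
    dev = arr - theta_bar
    # snap numerically-constant components to exactly zero deviation
    tiny = 1e-12 * np.maximum(1.0, np.abs(theta_bar))
    dev[:, np.all(np.abs(dev) <= tiny, axis=0)] = 0.0
    sigma = dev.T @ dev / (arr.shape[0] - 1)
    contrib = s * (sigma @ s)
    ref = float(np.var(lambda_decomposed(arr), ddof=1))
    return LTREContributions(
        design="random",
        contributions=dict(zip(THETA_NAMES, contrib)),
        total=float(contrib.sum()),
        reference=ref,
    )


def fixed_design(theta_t, theta_next, sens: SensitivityVector) -> LTREContributions:
    """Contributions of the change theta_t -> theta_{t+1} to delta lambda_t."""
    a = _as_theta_array(theta_t)
    b = _as_theta_array(theta_next)
    contrib = (b - a) * sens.values
    ref = float(lambda_decomposed(b) - lambda_decomposed(a))
    return LTREContributions(
        design="fixed",
        contributions=dict(zip(THETA_NAMES, contrib)),
        total=float(contrib.sum()),
        reference=ref,
    )


def fixed_design_series(theta_series) -> list[LTREContributions]:
    """Fixed-design LTRE for every year step, sensitivities at the series mean."""
    arr = _as_theta_array(theta_series)
    sens = sensitivities(arr.mean(axis=0))
    return [fixed_design(arr[t], arr[t + 1], sens) for t in range(arr.shape[0] - 1)]


def _growth_path(theta: np.ndarray, frozen_ny: np.ndarray | None = None):
    """Annual growth rates from the realized-rate recursion over a period.

    Population structure is re-propagated from the first year's n_Y unless a
    frozen n_Y path is supplied. Returns (lambda_t array, n_Y path used).
    """
    L = theta.shape[0]
    lam = np.empty(L)
    ny_path = np.empty(L)
    ny = theta[0, _N_Y_IDX] if frozen_ny is None else frozen_ny[0]
    for t in range(L):
        if frozen_ny is not None:
            ny = frozen_ny[t]
        ny_path[t] = ny
        (pB_Y, pB_A, CS_Y, CS_A, pNS, sN_Y, sN_A,
         sJ, sA, om_y, om_a, _) = theta[t]
        F_Y = pB_Y * CS_Y * pNS * sN_Y
        F_A = pB_A * CS_A * pNS * sN_A
        y_next = 0.5 * sJ * (ny * F_Y + (1.0 - ny) * F_A) + om_y
        a_next = sA + om_a
        lam[t] = y_next + a_next
        ny = y_next / lam[t] if lam[t] > 0 else 0.0
    return lam, ny_path


def _log_lambda_g(lam: np.ndarray) -> float:
    return float(np.mean(np.log(lam)))


#: theta components perturbable in the period design (all but n_Y).
PERTURBABLE = THETA_NAMES[:-1]


def realtime_elasticities(theta_series, period: tuple[int, int],
                          eps: float = 1e-4) -> ElasticitySet:
    """Numerical real-time elasticities of log lambda_g over one period.

    For each component, its within-period values are perturbed (mean: all
    scaled by 1+eps; SD: deviations from the period mean scaled by 1+eps),
    population structure is re-propagated through the projection recursion,
    and the elasticity is ``delta log lambda_g / eps``. The direct part is
    obtained with the structure path frozen at the baseline; the
    structure-mediated part is the remainder. Components with a zero period
    mean get a missing (NaN) mu-elasticity; components constant within the
    period get zero sigma-elasticities.
    """
    arr = _as_theta_array(theta_series)
    t0, t1 = period
    if not (0 <= t0 < t1 <= arr.shape[0]):
        raise ValueError("period must be a valid (start, stop) slice of the series")
    base = arr[t0:t1].copy()
    lam0, ny0 = _growth_path(base)
    ll0 = _log_lambda_g(lam0)

    e_mu_T, e_mu_s, e_sg_T, e_sg_s = {}, {}, {}, {}
    for i, name in enumerate(PERTURBABLE):
        mean_i = base[:, i].mean()
        # mean perturbation
        if mean_i == 0.0:
            e_mu_T[name] = float("nan")
            e_mu_s[name] = float("nan")
        else:
            pert = base.copy()
            pert[:, i] = base[:, i] * (1.0 + eps)
            ll_free = _log_lambda_g(_growth_path(pert)[0])
            ll_frozen = _log_lambda_g(_growth_path(pert, frozen_ny=ny0)[0])
            e_mu_T[name] = (ll_frozen - ll0) / eps
            e_mu_s[name] = (ll_free - ll0) / eps - e_mu_T[name]
        # SD perturbation
        dev = base[:, i] - mean_i
        if np.all(np.abs(dev) <= 1e-12 * max(1.0, abs(mean_i))):
            e_sg_T[name] = 0.0
            e_sg_s[name] = 0.0
        else:
            pert = base.copy()
            pert[:, i] = mean_i + (1.0 + eps) * dev
            ll_free = _log_lambda_g(_growth_path(pert)[0])
            ll_frozen = _log_lambda_g(_growth_path(pert, frozen_ny=ny0)[0])
            e_sg_T[name] = (ll_frozen - ll0) / eps
            e_sg_s[name] = (ll_free - ll0) / eps - e_sg_T[name]
    return ElasticitySet(e_mu_T, e_mu_s, e_sg_T, e_sg_s, ll0, (t0, t1))


def period_design(theta_series, period1: tuple[int, int],
                  period2: tuple[int, int], eps: float = 1e-4) -> LTREContributions:
    """Contributions of mean/SD changes between two periods to delta log lambda_g.

    Per component: ``(log mu_P2 - log mu_P1) * (e_mu_T + e_mu_struct) +
    (log sigma_P2 - log sigma_P1) * (e_sigma_T + e_sigma_struct)``, with
    elasticities averaged over the two periods. The two periods must have
    equal length. A component whose SD is zero in exactly one period has its
    sigma term flagged missing and excluded from the total (with a warning);
    components with equal SDs (including both zero) contribute zero through
    the sigma term.
    """
    arr = _as_theta_array(theta_series)
    if (period1[1] - period1[0]) != (period2[1] - period2[0]):
        raise ValueError("the two periods must have the same duration")
    e1 = realtime_elasticities(arr, period1, eps=eps)
    e2 = realtime_elasticities(arr, period2, eps=eps)
    p1 = arr[period1[0]:period1[1]]
    p2 = arr[period2[0]:period2[1]]

    def _sd(x):
        # snap numerically-constant series to an exact zero SD
        s = x.std(ddof=1)
        return 0.0 if s <= 1e-12 * max(1.0, abs(x.mean())) else s

    rows = []
    for i, name in enumerate(PERTURBABLE):
        mu1, mu2 = p1[:, i].mean(), p2[:, i].mean()
        sg1 = _sd(p1[:, i])
        sg2 = _sd(p2[:, i])
        emT = 0.5 * (e1.e_mu_T[name] + e2.e_mu_T[name])
        emS = 0.5 * (e1.e_mu_struct[name] + e2.e_mu_struct[name])
        esT = 0.5 * (e1.e_sigma_T[name] + e2.e_sigma_T[name])
        esS = 0.5 * (e1.e_sigma_struct[name] + e2.e_sigma_struct[name])
        if mu1 > 0 and mu2 > 0:
            dlmu = np.log(mu2) - np.log(mu1)
            mu_direct = dlmu * emT
            mu_indirect = dlmu * emS
        elif mu1 == mu2 == 0.0:
            mu_direct = mu_indirect = 0.0
        else:
            mu_direct = mu_indirect = float("nan")
        if sg1 > 0 and sg2 > 0:
            dlsg = np.log(sg2) - np.log(sg1)
            sg_direct = dlsg * esT
            sg_indirect = dlsg * esS
        elif sg1 == sg2:
            sg_direct = sg_indirect = 0.0
        else:
            warnings.warn(
                f"sigma of {name} is zero in exactly one period; its sigma "
                "term is flagged missing and excluded from the total")
            sg_direct = sg_indirect = float("nan")
        rows.append((name, mu_direct, mu_indirect, sg_direct, sg_indirect))

    comp = pd.DataFrame(
        rows, columns=["parameter", "mu_direct", "mu_indirect",
                       "sigma_direct", "sigma_indirect"]).set_index("parameter")
    contributions = {
        name: float(np.nansum(comp.loc[name].to_numpy()))
        if not np.all(np.isnan(comp.loc[name].to_numpy())) else float("nan")
        for name in comp.index
    }
    total = float(np.nansum(list(contributions.values())))
    reference = e2.log_lambda_g - e1.log_lambda_g
    return LTREContributions(
        design="period",
        contributions=contributions,
        total=total,
        reference=reference,
        components=comp,
    )


def posterior_ltre(theta_draws, design: str, *, period1=None, period2=None,
                   eps: float = 1e-4):
    """Apply one LTRE design per posterior draw and summarize.

    ``theta_draws`` has shape (n_draws, T, 12): each draw's realized theta
    series (rates from the draw, immigration rates and structure from the
    draw's latent states). Returns ``(per_draw, summary)`` where ``per_draw``
    is a tidy DataFrame (draw, design, parameter, group, value) and
    ``summary`` a DataFrame of posterior medians and 95% credible intervals
    per parameter and per group.
    """
    arr = np.asarray(theta_draws, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != len(THETA_NAMES):
        raise ValueError("theta_draws must have shape (n_draws, T, 12)")
    if design not in ("random", "fixed", "period"):
        raise ValueError(
            f"unknown design {design!r}; choose one of: random, fixed, period")
    records = []
    for d in range(arr.shape[0]):
        if design == "random":
            res = random_design(arr[d])
            items = res.contributions.items()
        elif design == "fixed":
            steps = fixed_design_series(arr[d])
            summed: dict[str, float] = {n: 0.0 for n in THETA_NAMES}
            for st in steps:
                for n, v in st.contributions.items():
                    summed[n] += v
            items = summed.items()
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = period_design(arr[d], period1, period2, eps=eps)
            items = res.contributions.items()
        for name, value in items:
            records.append((d, design, name, GROUPS[name], value))
    per_draw = pd.DataFrame(
        records, columns=["draw", "design", "parameter", "group", "value"])

    def _summary(frame, key):
        g = frame.groupby(key)["value"]
        return pd.DataFrame({
            "median": g.median(), "lower95": g.quantile(0.025),
            "upper95": g.quantile(0.975),
        })

    group_totals = per_draw.groupby(["draw", "group"], as_index=False)["value"].sum()
    summary = pd.concat({
        "parameter": _summary(per_draw, "parameter"),
        "group": _summary(group_totals, "group"),
    }, names=["level", "name"])
    return per_draw, summary
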