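"""Likelihood components: CJS, clutch, nest fate, counts, transitions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from nestipm import _mcmc, core
from nestipm import io as nio
from nestipm import likelihoods as lk

from oracles import cjs_enumeration_loglik, random_cjs_params, random_histories


def histories_from(rows, T, y0=2000):
    """rows: list of (ring_age, first_idx, detection_list_from_first)."""
    det = np.zeros((len(rows), T), dtype=np.int8)
    first, ages = [], []
    for i, (age, f, vec) in enumerate(rows):
        det[i, f:f + len(vec)] = vec
        first.append(f)
        ages.append(age)
    return nio.CaptureHistories(
        individuals=np.array([f"i{i}" for i in range(len(rows))]),
        ring_age=np.array(ages), first_year=np.array(first),
        detections=det, years=np.arange(y0, y0 + T))


class TestLinearPredictor:
    def test_logit_identity(self):
        m = lk.LinkModel(intercept=0.0)
        assert lk.linear_predictor(m, 0, 0) == pytest.approx(0.5)

    def test_log_link(self):
        m = lk.LinkModel(intercept=np.log(6.5), link="log")
        assert lk.linear_predictor(m, 0, 0) == pytest.approx(6.5)

    def test_rain_slope(self):
        m = lk.LinkModel(intercept=0.0, beta_rain=-1.0)
        got = lk.linear_predictor(m, 0, 0, {"rain": 1.0})
        assert got == pytest.approx(0.2689, abs=1e-4)

    def test_missing_covariate_is_error(self):
        m = lk.LinkModel(intercept=0.0, beta_rain=-1.0)
        with pytest.raises(ValueError, match="missing"):
            lk.linear_predictor(m, 0, 3, {"rain": np.nan})


class TestCJS:
    def test_hand_product_seen_again(self):
        h = histories_from([("adult", 0, [1, 0, 1])], T=3)
        ll = lk.cjs_loglik(h, sJ=[0.3] * 3, sA=[0.5] * 3,
                           pB=np.full((2, 3), 0.4), pCapB=[1.0] * 3)
        assert ll == pytest.approx(np.log(0.5 * 0.6 * 0.5 * 0.4))

    def test_two_term_enumeration(self):
        h = histories_from([("adult", 0, [1, 0, 0])], T=3)
        ll = lk.cjs_loglik(h, sJ=[0.3] * 3, sA=[0.5] * 3,
                           pB=np.full((2, 3), 0.4), pCapB=[1.0] * 3)
        assert ll == pytest.approx(np.log(0.74))

    def test_empty_history_set(self):
        h = histories_from([], T=4)
        assert lk.cjs_loglik(h, [0.3] * 4, [0.5] * 4,
                             np.full((2, 4), 0.4), [1.0] * 4) == 0.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            T = int(rng.integers(3, 7))
            h = random_histories(rng, T, int(rng.integers(5, 20)))
            p = random_cjs_params(rng, T)
            assert lk.cjs_loglik(h, **p) == pytest.approx(
                cjs_enumeration_loglik(h, **p), abs=1e-10)

    def test_equals_marray_multinomial(self, rng):
        for _ in range(5):
            T = int(rng.integers(4, 9))
            h = random_histories(rng, T, 30)
            p = random_cjs_params(rng, T)
            marr = lk.build_marrays(h)
            assert lk.marray_loglik(*marr, **p) == pytest.approx(
                lk.cjs_loglik(h, **p), abs=1e-8)

    def test_sampler_kernel_agrees(self, rng):
        """The compiled m-array kernel matches the reference implementation."""
        T = 8
        h = random_histories(rng, T, 40)
        p = random_cjs_params(rng, T)
        m_j, nv_j, m_a, nv_a = lk.build_marrays(h)
        got = _mcmc._ll_cjs(
            (nv_j > 0) | m_j.any(axis=1), m_j.astype(float),
            nv_j.astype(float),
            (nv_a > 0) | m_a.any(axis=1), m_a.astype(float),
            nv_a.astype(float),
            p["sJ"], p["sA"], p["pB"][0] * p["pCapB"], p["pB"][1] * p["pCapB"])
        assert got == pytest.approx(lk.cjs_loglik(h, **p), abs=1e-8)


class TestClutch:
    def test_poisson_pmf(self):
        CS = np.full((2, 1), 6.0)
        ll = lk.clutch_loglik([1], [0], [6], CS)
        assert ll == pytest.approx(stats.poisson.logpmf(6, 6.0))

    def test_vanishing_mean_guarded(self):
        ll = lk.clutch_loglik([0], [0], [3], np.full((2, 1), 1e-18))
        assert np.isfinite(ll) and ll < -50

    def test_additivity(self, rng):
        CS = rng.uniform(4, 8, (2, 5))
        a = rng.integers(0, 2, 20)
        t = rng.integers(0, 5, 20)
        c = rng.integers(1, 10, 20)
        total = lk.clutch_loglik(a, t, c, CS)
        parts = sum(lk.clutch_loglik([a[i]], [t[i]], [c[i]], CS)
                    for i in range(20))
        assert total == pytest.approx(parts)


class TestNestFate:
    def test_certain_success(self):
        ll = lk.nest_fate_loglik([0], [0], [6], [6], [1.0], np.ones((2, 1)))
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_zero_fledged_mixture(self):
        ll = lk.nest_fate_loglik([0], [0], [1], [0], [0.8],
                                 np.full((2, 1), 0.5))
        assert ll == pytest.approx(np.log(0.2 + 0.8 * 0.5))

    def test_mle_recovers_truth(self, rng):
        """Maximum likelihood on simulated fates lands near the generator."""
        true_pns, true_sn = 0.85, 0.9
        n = 4000
        clutch = rng.integers(4, 9, n)
        success = rng.random(n) < true_pns
        fledged = np.where(success, rng.binomial(clutch, true_sn), 0)

        def nll(z):
            pns, sn = z
            if not (0 < pns < 1 and 0 < sn < 1):
                return 1e12
            return -lk.nest_fate_loglik(
                np.zeros(n, int), np.zeros(n, int), clutch, fledged,
                np.array([pns]), np.full((2, 1), sn))

        res = optimize.minimize(nll, [0.7, 0.7], method="Nelder-Mead")
        se = 3.0 / np.sqrt(n)
        assert abs(res.x[0] - true_pns) < 3 * se
        assert abs(res.x[1] - true_sn) < 3 * se


def make_rates(T, **kw):
    p = dict(pB=0.8, CS=6.0, pNS=0.85, sN=0.9, sJ=0.12, sA=0.5)
    p.update(kw)
    return core.VitalRateSeries(
        pB=np.full((2, T), p["pB"]), CS=np.full((2, T), p["CS"]),
        pNS=np.full(T, p["pNS"]), sN=np.full((2, T), p["sN"]),
        sJ=np.full(T, p["sJ"]), sA=np.full(T, p["sA"]))


def make_params(T, omega=20.0):
    mk = lambda v, link="logit": lk.LinkModel(intercept=v, link=link)
    return lk.ParameterSet(
        pB=mk(np.zeros(2)), CS=mk(np.log([6.0, 6.0]), "log"),
        pNS=mk(0.0), sN=mk(np.zeros(2)), sJ=mk(0.0), sA=mk(0.0),
        omega=np.full((2, T), omega / 2))


class TestCounts:
    def test_matches_poisson_logpmf(self):
        T = 1
        rates = make_rates(T, pB=1.0, CS=5.0, pNS=1.0, sN=1.0)
        counts = pd.DataFrame({
            "first_clutches": [10], "eggs": [50], "fledglings": [50],
            "newly_ringed_adults": [0]})
        N = np.array([[4], [6]])
        ll = lk.counts_loglik(counts, N, make_params(T), rates, [1.0])
        expected = (stats.poisson.logpmf(10, 10)
                    + stats.poisson.logpmf(50, 50.0) * 2)
        assert ll == pytest.approx(expected)

    def test_zero_observed_zero_expected(self):
        T = 1
        rates = make_rates(T, pB=0.0)
        counts = pd.DataFrame({
            "first_clutches": [0], "eggs": [0], "fledglings": [0],
            "newly_ringed_adults": [0]})
        ll = lk.counts_loglik(counts, np.array([[5], [5]]), make_params(T),
                              rates, [1.0])
        assert ll == 0.0

    def test_truth_dominates_perturbed_rates(self, rng):
        """Counts simulated at truth score above +-20%-perturbed rates."""
        T = 25
        rates = make_rates(T)
        wins = {"up": 0, "down": 0}
        n_sim = 100
        for k in range(n_sim):
            ens = core.stochastic_project(rates, np.full((2, T), 10.0),
                                          (60, 120), seed=1000 + k, reps=1)
            N = ens.N[0]
            params = make_params(T)
            mu_b = (N * rates.pB).sum(axis=0)
            mu_e = (N * rates.pB * rates.CS).sum(axis=0)
            mu_f = (N * rates.pB * rates.CS * rates.pNS[None] * rates.sN).sum(axis=0)
            counts = pd.DataFrame({
                "first_clutches": rng.poisson(mu_b),
                "eggs": rng.poisson(mu_e),
                "fledglings": rng.poisson(mu_f),
                "newly_ringed_adults": rng.poisson(20.0, T)})
            ll_true = lk.counts_loglik(counts, N, params, rates, np.ones(T))
            for tag, fac in (("up", 1.2), ("down", 0.8)):
                pert = make_rates(T, pB=0.8 * fac)
                ll_pert = lk.counts_loglik(counts, N, params, pert, np.ones(T))
                wins[tag] += ll_true > ll_pert
        assert wins["up"] >= 95 and wins["down"] >= 95


class TestStateTransition:
    def test_deterministic_limit(self):
        T = 3
        rates = make_rates(T, pB=0.0, sJ=0.0, sA=0.0)
        omega = np.zeros((2, T))
        zeroN = np.array([[5, 0, 0], [5, 0, 0]])
        ll = lk.state_transition_loglik(zeroN, np.zeros((2, T)), rates, omega)
        assert np.isfinite(ll)
        bad = np.array([[5, 1, 0], [5, 0, 0]])
        assert lk.state_transition_loglik(bad, np.zeros((2, T)), rates,
                                          omega) == -np.inf

    def test_survivors_exceeding_trials_guarded(self):
        T = 2
        rates = make_rates(T)
        N = np.array([[5, 0], [5, 40]])
        ll = lk.state_transition_loglik(N, np.zeros((2, T)), rates,
                                        np.zeros((2, T)))
        assert ll == -np.inf

    def test_simulated_trajectories_finite_at_truth(self):
        T = 10
        rates = make_rates(T)
        imm = np.full((2, T), 12.0)
        omega = np.zeros((2, T))
        omega[:, 1:] = 12.0
        for k in range(100):
            ens = core.stochastic_project(rates, imm, (50, 100),
                                          seed=2000 + k, reps=1)
            ll = lk.state_transition_loglik(
                ens.N[0], ens.imm[0], rates, omega)
            assert np.isfinite(ll)


def test_sampler_kernels_match_reference_on_records(rng):
    """Likelihood *differences* from the compiled sufficient-statistic
    kernels equal the per-record reference implementations (the kernels drop
    data-only additive constants, so deltas are the comparable quantity)."""
    T = 4
    n = 60
    a_idx = rng.integers(0, 2, n)
    t_idx = rng.integers(0, T, n)
    clutch = rng.integers(3, 9, n)
    fledged = np.where(rng.random(n) < 0.8,
                       rng.binomial(clutch, 0.85), 0)
    # sufficient statistics as the fitting bundle builds them
    ncl = np.zeros((2, T))
    scl = np.zeros((2, T))
    nsucc = np.zeros((2, T))
    sumf = np.zeros((2, T))
    sumcf = np.zeros((2, T))
    failc = np.zeros((2, T, int(clutch.max()) + 1))
    for a, t, c, f in zip(a_idx, t_idx, clutch, fledged):
        ncl[a, t] += 1
        scl[a, t] += c
        if f > 0:
            nsucc[a, t] += 1
            sumf[a, t] += f
            sumcf[a, t] += c - f
        else:
            failc[a, t, c] += 1

    for _ in range(3):
        cs1, cs2 = rng.uniform(4, 8, 2)
        d_kernel = (_mcmc._ll_clutch_all(np.full(T, cs1), np.full(T, cs1),
                                         ncl, scl)
                    - _mcmc._ll_clutch_all(np.full(T, cs2), np.full(T, cs2),
                                           ncl, scl))
        d_ref = (lk.clutch_loglik(a_idx, t_idx, clutch, np.full((2, T), cs1))
                 - lk.clutch_loglik(a_idx, t_idx, clutch, np.full((2, T), cs2)))
        assert d_kernel == pytest.approx(d_ref, rel=1e-10)

        pns1, pns2 = rng.uniform(0.6, 0.95, 2)
        sn1, sn2 = rng.uniform(0.6, 0.95, 2)
        d_kernel = (_mcmc._ll_nest_all(np.full(T, pns1), np.full(T, sn1),
                                       np.full(T, sn1), nsucc, sumf, sumcf,
                                       failc)
                    - _mcmc._ll_nest_all(np.full(T, pns2), np.full(T, sn2),
                                         np.full(T, sn2), nsucc, sumf, sumcf,
                                         failc))
        d_ref = (lk.nest_fate_loglik(a_idx, t_idx, clutch, fledged,
                                     np.full(T, pns1), np.full((2, T), sn1))
                 - lk.nest_fate_loglik(a_idx, t_idx, clutch, fledged,
                                       np.full(T, pns2), np.full((2, T), sn2)))
        assert d_kernel == pytest.approx(d_ref, rel=1e-10)
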