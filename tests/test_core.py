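"""Demographic core: projection, growth decomposition, stochastic kernels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestipm import core

THETA_OK = dict(pB_Y=0.7, pB_A=0.9, CS_Y=6.0, CS_A=6.5, pNS=0.85,
                sN_Y=0.85, sN_A=0.9, sJ=0.12, sA=0.5)


def const_rates(T, **kw):
    p = dict(pB=0.8, CS=6.0, pNS=0.85, sN=0.9, sJ=0.12, sA=0.5)
    p.update(kw)
    return core.VitalRateSeries(
        pB=np.full((2, T), p["pB"]), CS=np.full((2, T), p["CS"]),
        pNS=np.full(T, p["pNS"]), sN=np.full((2, T), p["sN"]),
        sJ=np.full(T, p["sJ"]), sA=np.full(T, p["sA"]))


@pytest.mark.parametrize("args,expected", [
    ((1, 6, 1, 1), 6.0),
    ((0, 6.5, 0.9, 0.9), 0.0),
    ((0.9, 6.5, 0.8, 0.9), 4.212),
])
def test_fecundity_product(args, expected):
    assert core.fecundity(*args) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [
    dict(pB=1.2), dict(pNS=-0.1), dict(sN=2.0), dict(CS=-1.0),
])
def test_fecundity_rejects_out_of_bounds(bad):
    args = dict(pB=0.9, CS=6.0, pNS=0.8, sN=0.9)
    args.update(bad)
    with pytest.raises(ValueError):
        core.fecundity(**args)


def test_projection_matches_printed_example():
    th = core.ThetaVector(pB_Y=1, pB_A=1, CS_Y=4, CS_A=4, pNS=1, sN_Y=1,
                          sN_A=1, sJ=0.25, sA=0.5)
    assert core.project_expectation(100, 100, th, (10, 20)) == (110.0, 120.0)
    th0 = core.ThetaVector(**{**THETA_OK, "sJ": 0.0, "sA": 0.0})
    assert core.project_expectation(100, 100, th0, (0, 0)) == (0.0, 0.0)


def test_projection_equals_matrix_product(rng):
    """The expectation recursion is the printed 2x2 matrix-vector product."""
    for _ in range(25):
        th = core.ThetaVector(
            pB_Y=rng.uniform(0, 1), pB_A=rng.uniform(0, 1),
            CS_Y=rng.uniform(0, 10), CS_A=rng.uniform(0, 10),
            pNS=rng.uniform(0, 1), sN_Y=rng.uniform(0, 1),
            sN_A=rng.uniform(0, 1), sJ=rng.uniform(0, 1),
            sA=rng.uniform(0, 1))
        n = rng.uniform(0, 500, size=2)
        imm = rng.uniform(0, 50, size=2)
        f_y = th.pB_Y * th.CS_Y * th.pNS * th.sN_Y
        f_a = th.pB_A * th.CS_A * th.pNS * th.sN_A
        A = np.array([[0.5 * f_y * th.sJ, 0.5 * f_a * th.sJ],
                      [th.sA, th.sA]])
        expected = A @ n + imm
        got = core.project_expectation(n[0], n[1], th, tuple(imm))
        np.testing.assert_allclose(got, expected, rtol=1e-12)


@given(alpha=st.floats(0.0, 10.0))
@settings(deadline=None, max_examples=25)
def test_projection_linearity(alpha):
    th = core.ThetaVector(**THETA_OK)
    base = core.project_expectation(40, 80, th, (5, 10))
    scaled = core.project_expectation(alpha * 40, alpha * 80, th,
                                      (alpha * 5, alpha * 10))
    np.testing.assert_allclose(scaled, (alpha * base[0], alpha * base[1]),
                               rtol=1e-9, atol=1e-9)


@pytest.mark.parametrize("series,expected", [
    ([100, 110, 99], [1.1, 0.9]),
    ([50, 50, 50], [1.0, 1.0]),
    ([200, 230], [1.15]),
])
def test_realized_growth(series, expected):
    np.testing.assert_allclose(core.realized_growth(series), expected)


def test_realized_growth_flags_zero_years():
    lam = core.realized_growth([10, 0, 5])
    assert lam[0] == 0.0
    assert np.isnan(lam[1])


def test_lambda_decomposed_plugin():
    th = core.ThetaVector(pB_Y=1, pB_A=1, CS_Y=4, CS_A=4, pNS=1, sN_Y=1,
                          sN_A=1, sJ=0.25, sA=0.5, omega_Y=0.05,
                          omega_A=0.10, n_Y=0.5)
    assert core.lambda_decomposed(th) == pytest.approx(1.15)
    assert core.lambda_decomposed(np.zeros(12)) == 0.0
    with pytest.raises(ValueError):
        core.lambda_decomposed(core.ThetaVector(**THETA_OK, n_Y=1.5))


def test_decomposition_identity_on_simulated_trajectories():
    """Realized per-capita components reproduce realized growth exactly."""
    T = 15
    rates = const_rates(T)
    ens = core.stochastic_project(rates, np.full((2, T), 25.0), (60, 120),
                                  seed=5, reps=40)
    theta = core.realized_theta(ens)
    lam = core.lambda_decomposed(theta)
    ntot = ens.ntot.astype(float)
    expected = ntot[:, 1:] / np.maximum(ntot[:, :-1], 1.0)
    ok = ntot[:, :-1] > 0
    np.testing.assert_allclose(lam[ok], expected[ok], rtol=0, atol=1e-13)


@given(data=st.data())
@settings(deadline=None, max_examples=40)
def test_lambda_monotone_in_every_rate_component(data):
    """Growth is non-decreasing in every vital/immigration rate.

    Age structure (n_Y) is excluded: its effect has the sign of F_Y - F_A,
    so shifting weight towards the less fecund class lowers growth.
    """
    base = np.array([0.5, 0.7, 5.0, 6.0, 0.8, 0.8, 0.85, 0.15, 0.45,
                     0.05, 0.2, 0.4])
    i = data.draw(st.integers(0, 10))
    hi = {2: 10.0, 3: 10.0, 9: 1.0, 10: 1.0}.get(i, 1.0)
    delta = data.draw(st.floats(0.0, float(hi - base[i])))
    bumped = base.copy()
    bumped[i] += delta
    assert core.lambda_decomposed(bumped) >= core.lambda_decomposed(base) - 1e-12


@pytest.mark.parametrize("N,pB,expect_B,expect_f", [
    ((50, 150), (0.5, 0.9), 160.0, 0.8),
    ((50, 150), (1.0, 1.0), 200.0, 1.0),
    ((50, 150), (0.0, 0.0), 0.0, 0.0),
])
def test_breeding_population(N, pB, expect_B, expect_f):
    B, f = core.breeding_population(np.array(N, float), np.array(pB))
    assert B == expect_B
    assert f == expect_f


def test_breeding_population_zero_total_flagged():
    _, f = core.breeding_population(np.zeros(2), np.array([0.5, 0.9]))
    assert np.isnan(f)


def test_stochastic_project_deterministic_and_extinct():
    T = 6
    zero = const_rates(T, pB=0.0, sJ=0.0, sA=0.0)
    ens = core.stochastic_project(zero, np.zeros((2, T)), (30, 60),
                                  seed=1, reps=20)
    assert (ens.ntot[:, 1:] == 0).all()
    rates = const_rates(T)
    a = core.stochastic_project(rates, np.full((2, T), 10.0), (30, 60),
                                seed=9, reps=50)
    b = core.stochastic_project(rates, np.full((2, T), 10.0), (30, 60),
                                seed=9, reps=50)
    assert np.array_equal(a.N, b.N) and np.array_equal(a.imm, b.imm)


def test_stochastic_project_mean_matches_expectation():
    """Ensemble means converge to the deterministic expectation recursion."""
    T = 8
    rates = const_rates(T)
    imm = np.full((2, T), 15.0)
    reps = 10_000
    ens = core.stochastic_project(rates, imm, (80, 160), seed=3, reps=reps)
    th = core.ThetaVector(pB_Y=0.8, pB_A=0.8, CS_Y=6.0, CS_A=6.0, pNS=0.85,
                          sN_Y=0.9, sN_A=0.9, sJ=0.12, sA=0.5)
    ny, na = 80.0, 160.0
    for t in range(1, T):
        ny, na = core.project_expectation(ny, na, th, (15.0, 15.0))
        mean = ens.ntot[:, t].mean()
        se = ens.ntot[:, t].std(ddof=1) / np.sqrt(reps)
        assert abs(mean - (ny + na)) < 3 * max(se, 1e-9)


def test_growth_covariation_extremes(rng):
    years = np.arange(2000, 2020)
    base = 100 * np.exp(np.cumsum(rng.normal(0, 0.2, len(years))))
    mirrored = 100 * np.exp(-np.log(base / 100))
    df = pd.DataFrame({"a": base, "b": base, "c": mirrored}, index=years)
    corr = core.growth_covariation(df)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)


def test_growth_covariation_independent_series_near_zero(rng):
    years = np.arange(1000)
    df = pd.DataFrame(
        {k: 100 * np.exp(np.cumsum(rng.normal(0, 0.1, 1000)))
         for k in "ab"}, index=years)
    corr = core.growth_covariation(df)
    assert abs(corr.loc["a", "b"]) < 0.1


def test_growth_covariation_requires_overlap():
    years = np.arange(2000, 2010)
    a = pd.Series(np.linspace(100, 200, 10), index=years)
    b = a.copy()
    b.iloc[:-3] = np.nan  # only 2 overlapping changes remain
    corr = core.growth_covariation(pd.DataFrame({"a": a, "b": b}))
    assert np.isnan(corr.loc["a", "b"])


def test_population_trend_examples():
    assert core.population_trend(np.arange(10.0) + 1) == pytest.approx(1.0)
    assert core.population_trend(np.arange(10.0)[::-1] + 1) == pytest.approx(-1.0)
    assert core.population_trend([5.0, 5.0, 5.0, 5.0]) == 0.0
    # brute-force Spearman: correlation of the rank vectors
    x = np.array([5.0, 1.0, 4.0, 2.0, 3.0])
    ranks = x.argsort().argsort().astype(float)
    years = np.arange(5.0)
    expected = np.corrcoef(ranks, years)[0, 1]
    assert core.population_trend(x) == pytest.approx(expected)
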