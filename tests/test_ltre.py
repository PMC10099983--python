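"""Sensitivities and the random-, fixed- and period-design transient LTREs."""

import numpy as np
import pytest

from nestipm import core, ltre

BASE = np.array([0.65, 0.9, 6.0, 6.5, 0.85, 0.85, 0.9, 0.1, 0.45,
                 0.05, 0.3, 0.35])


def random_theta(rng):
    th = np.empty(12)
    th[[0, 1, 4, 5, 6, 7, 8]] = rng.uniform(0.05, 0.95, 7)
    th[[2, 3]] = rng.uniform(1.0, 9.0, 2)
    th[[9, 10]] = rng.uniform(0.0, 0.5, 2)
    th[11] = rng.uniform(0.05, 0.95)
    return th


def fd_gradient(theta, h=1e-6):
    out = np.empty(12)
    for i in range(12):
        a, b = theta.copy(), theta.copy()
        a[i] -= h
        b[i] += h
        out[i] = (core.lambda_decomposed(b) - core.lambda_decomposed(a)) / (2 * h)
    return out


class TestSensitivities:
    def test_affine_components_are_one(self, rng):
        for _ in range(5):
            s = ltre.sensitivities(random_theta(rng))
            assert s["sA"] == 1.0
            assert s["omega_Y"] == 1.0 and s["omega_A"] == 1.0

    def test_symmetric_fecundity(self):
        th = BASE.copy()
        th[[0, 1]] = 1.0   # pB
        th[[2, 3]] = 4.0   # CS
        th[4] = 1.0        # pNS
        th[[5, 6]] = 1.0   # sN
        th[7] = 0.5        # sJ -> F_Y = F_A = 4
        th[11] = 0.5
        s = ltre.sensitivities(th)
        assert s["sJ"] == pytest.approx(2.0)
        assert s["n_Y"] == pytest.approx(0.0)

    def test_matches_finite_differences(self, rng):
        for _ in range(10):
            th = random_theta(rng)
            s = ltre.sensitivities(th).values
            fd = fd_gradient(th)
            np.testing.assert_allclose(s, fd, rtol=1e-6, atol=1e-9)

    def test_out_of_bounds_rejected(self):
        bad = BASE.copy()
        bad[4] = 1.4
        with pytest.raises(ValueError):
            ltre.sensitivities(bad)


class TestRandomDesign:
    def test_constant_series_all_zero(self):
        series = np.tile(BASE, (10, 1))
        res = ltre.random_design(series)
        assert all(v == 0.0 for v in res.contributions.values())
        assert res.total == 0.0

    def test_single_varying_component(self, rng):
        series = np.tile(BASE, (200, 1))
        series[:, 8] = 0.45 + rng.normal(0, 0.05, 200)
        series[:, 8] = np.clip(series[:, 8], 0, 1)
        var_sa = np.var(series[:, 8], ddof=1)
        res = ltre.random_design(series)
        assert res.contributions["sA"] == pytest.approx(var_sa)
        others = [v for k, v in res.contributions.items() if k != "sA"]
        assert np.allclose(others, 0.0)
        assert res.total == pytest.approx(var_sa)

    def test_total_approximates_variance_of_growth(self, rng):
        series = np.tile(BASE, (200, 1))
        for i in range(12):
            cv = 0.08
            series[:, i] *= 1.0 + rng.normal(0, cv, 200)
        series[:, [0, 1, 4, 5, 6, 7, 8, 11]] = np.clip(
            series[:, [0, 1, 4, 5, 6, 7, 8, 11]], 0, 1)
        res = ltre.random_design(series)
        assert res.total == pytest.approx(res.reference, rel=0.10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            ltre.random_design(np.tile(BASE, (2, 1)))


class TestFixedDesign:
    def test_no_change_no_contribution(self):
        sens = ltre.sensitivities(BASE)
        res = ltre.fixed_design(BASE, BASE, sens)
        assert res.total == 0.0 and res.reference == 0.0

    def test_affine_component_exact(self):
        nxt = BASE.copy()
        nxt[8] = 0.55
        res = ltre.fixed_design(BASE, nxt, ltre.sensitivities(BASE))
        assert res.contributions["sA"] == pytest.approx(0.1)
        assert res.total == pytest.approx(res.reference)

    def test_small_perturbations_match_delta_lambda(self, rng):
        """Sensitivities at the two-point mean make the total track the true
        change to third order."""
        for _ in range(20):
            th = random_theta(rng)
            nxt = th * (1.0 + rng.uniform(-0.05, 0.05, 12))
            nxt[11] = min(nxt[11], 1.0)
            sens = ltre.sensitivities(0.5 * (th + nxt))
            res = ltre.fixed_design(th, nxt, sens)
            assert abs(res.total - res.reference) <= 0.05 * abs(res.reference)


class TestRealtimeElasticities:
    def test_constant_parameter_zero_sigma_elasticity(self):
        series = np.tile(BASE, (20, 1))
        es = ltre.realtime_elasticities(series, (0, 20))
        assert all(v == 0.0 for v in es.e_sigma_T.values())
        assert all(v == 0.0 for v in es.e_sigma_struct.values())

    def test_adult_survival_affine_check(self):
        """With frozen structure the sA mean-elasticity is mean(sA_t/lambda_t);
        at structural equilibrium (constant lambda path) that is sA/lambda_g."""
        series = np.tile(BASE, (60, 1))
        # equilibrate the age structure so lambda_t is constant along the path
        _, ny_path = ltre._growth_path(series)
        series[:, 11] = ny_path[-1]
        es = ltre.realtime_elasticities(series, (20, 60))
        lam_g = np.exp(es.log_lambda_g)
        assert es.e_mu_T["sA"] == pytest.approx(BASE[8] / lam_g, abs=1e-3)

    def test_zero_mean_flagged_missing(self):
        series = np.tile(BASE, (10, 1))
        series[:, 9] = 0.0
        es = ltre.realtime_elasticities(series, (0, 10))
        assert np.isnan(es.e_mu_T["omega_Y"])

    def test_first_order_stability_in_epsilon(self, rng):
        series = np.tile(BASE, (15, 1))
        series *= 1.0 + rng.normal(0, 0.03, series.shape)
        series[:, 11] = np.clip(series[:, 11], 0, 1)
        e1 = ltre.realtime_elasticities(series, (0, 15), eps=1e-4)
        e2 = ltre.realtime_elasticities(series, (0, 15), eps=5e-5)
        for k in e1.e_mu_T:
            a, b = e1.e_mu_T[k], e2.e_mu_T[k]
            if np.isnan(a):
                continue
            assert abs(a - b) <= 1e-3 * max(1.0, abs(a))


class TestPeriodDesign:
    def test_identical_periods_zero(self):
        series = np.tile(BASE, (30, 1))
        res = ltre.period_design(series, (0, 15), (15, 30))
        assert all(v == 0.0 for v in res.contributions.values())
        assert res.total == 0.0

    def test_mean_shift_in_survival(self):
        series = np.tile(BASE, (40, 1))
        series[20:, 8] = 0.55
        res = ltre.period_design(series, (0, 20), (20, 40))
        assert res.total == pytest.approx(res.reference, rel=0.05)
        assert abs(res.contributions["sA"]) > 10 * max(
            abs(v) for k, v in res.contributions.items() if k != "sA")

    def test_component_split_sums_exactly(self, rng):
        series = np.tile(BASE, (30, 1))
        series *= 1.0 + rng.normal(0, 0.05, series.shape)
        series[:, 11] = np.clip(series[:, 11], 0, 1)
        res = ltre.period_design(series, (0, 15), (15, 30))
        for name in res.components.index:
            parts = res.components.loc[name].to_numpy()
            assert np.nansum(parts) == pytest.approx(
                res.contributions[name], abs=1e-12)

    def test_unequal_periods_rejected(self):
        series = np.tile(BASE, (30, 1))
        with pytest.raises(ValueError, match="duration"):
            ltre.period_design(series, (0, 10), (10, 30))


class TestPosteriorLTRE:
    def test_degenerate_posterior_zero_width(self, rng):
        series = np.tile(BASE, (15, 1))
        series *= 1.0 + rng.normal(0, 0.05, series.shape)
        series[:, 11] = np.clip(series[:, 11], 0, 1)
        theta_draws = np.tile(series, (8, 1, 1))
        per_draw, summary = ltre.posterior_ltre(theta_draws, "random")
        widths = (summary.loc["parameter"]["upper95"]
                  - summary.loc["parameter"]["lower95"])
        assert (widths.abs() < 1e-12).all()

    def test_unknown_design_lists_options(self):
        with pytest.raises(ValueError, match="random, fixed, period"):
            ltre.posterior_ltre(np.zeros((2, 5, 12)), "prospective")

    def test_symmetric_component_swap(self, rng):
        """Swapping the two immigration columns swaps their contributions
        (identical sensitivities), leaving everything else unchanged."""
        series = np.tile(BASE, (40, 1))
        series[:, 9] = rng.uniform(0.0, 0.2, 40)
        series[:, 10] = rng.uniform(0.1, 0.4, 40)
        res = ltre.random_design(series)
        swapped = series.copy()
        swapped[:, [9, 10]] = swapped[:, [10, 9]]
        res2 = ltre.random_design(swapped)
        assert res2.contributions["omega_Y"] == pytest.approx(
            res.contributions["omega_A"])
        assert res2.contributions["omega_A"] == pytest.approx(
            res.contributions["omega_Y"])
        for k in ("sA", "sJ", "pNS"):
            assert res2.contributions[k] == pytest.approx(
                res.contributions[k], abs=1e-15)

    def test_group_sums_linear_in_draws(self, rng):
        theta_draws = np.stack([np.tile(random_theta(rng), (10, 1))
                                * (1 + rng.normal(0, 0.03, (10, 12)))
                                for _ in range(6)])
        theta_draws[..., 11] = np.clip(theta_draws[..., 11], 0, 1)
        per_draw, summary = ltre.posterior_ltre(theta_draws, "fixed")
        # group means equal the sum of member parameter means
        gmean = per_draw.groupby(["draw", "group"])["value"].sum() \
            .groupby("group").mean()
        pmean = per_draw.groupby("parameter")["value"].mean()
        for g in gmean.index:
            members = [k for k, v in ltre.GROUPS.items() if v == g]
            assert gmean[g] == pytest.approx(sum(pmean[m] for m in members))
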