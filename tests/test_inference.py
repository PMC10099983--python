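"""Priors, MCMC fitting, convergence diagnostics and model testing."""

import numpy as np
import pytest

from nestipm import _mcmc
from nestipm import inference as inf
from nestipm import simulate as sim


class TestPriors:
    def test_default_bounds(self):
        ps = inf.default_priors()
        assert ps.bounds("pB_Y") == (0.0, 1.0)
        assert ps.bounds("CS_A") == (0.0, 12.0)
        assert ps.bounds("beta_rain_sJ") == (-5.0, 5.0)
        assert ps.bounds("sigma_sA") == (0.0, 3.0)
        assert ps.bounds("q") == (0.0, 1.0)

    def test_override(self):
        ps = inf.default_priors({"CS_A": (2.0, 9.0)})
        assert ps.bounds("CS_A") == (2.0, 9.0)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            inf.default_priors({"sA": (0.9, 0.1)})

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            inf.default_priors({"sZ": (0, 1)})


class TestFitConfig:
    def test_defaults_mirror_full_run(self):
        cfg = inf.FitConfig()
        assert (cfg.n_chains, cfg.n_iter, cfg.n_burnin, cfg.thin) == \
            (4, 200_000, 50_000, 30)

    def test_test_profile(self):
        cfg = inf.FitConfig.test_profile()
        assert (cfg.n_chains, cfg.n_iter, cfg.n_burnin, cfg.thin) == \
            (3, 20_000, 5_000, 10)

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            inf.FitConfig(n_iter=100, n_burnin=100)


class TestGelmanRubin:
    def test_identical_chains(self, rng):
        chain = rng.normal(size=100)
        rhat = inf.gelman_rubin(np.stack([chain, chain]))
        assert rhat == pytest.approx(np.sqrt(99 / 100))

    def test_separated_chains_closed_form(self, rng):
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(10.0, 1.0, 200)
        arr = np.stack([a, b])
        m, n = arr.shape
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert inf.gelman_rubin(arr) == pytest.approx(expected)
        assert inf.gelman_rubin(arr) > 3.0

    def test_white_noise_near_one(self, rng):
        arr = rng.normal(size=(2, 10_000))
        assert 0.99 < inf.gelman_rubin(arr) < 1.01

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="multi-chain"):
            inf.gelman_rubin(rng.normal(size=(1, 100)))


class TestFitIPM:
    def test_contract_finite_draws_and_manifest(self, tiny_fit):
        assert np.isfinite(tiny_fit.draws).all()
        assert len(tiny_fit.names) == tiny_fit.draws.shape[2]
        # every sampled quantity maps to a manifest entry
        for name in tiny_fit.names:
            base = name.split("[")[0]
            assert base in tiny_fit.manifest

    def test_draws_respect_prior_support(self, tiny_fit, small_bundle):
        priors = inf._resolve_priors(small_bundle, tiny_fit.config)
        flat = tiny_fit.draws.reshape(-1, tiny_fit.draws.shape[2])
        for j, name in enumerate(inf.TOP_NAMES):
            assert (flat[:, j] >= priors.lo[j]).all()
            assert (flat[:, j] <= priors.hi[j]).all()
        om = flat[:, tiny_fit.index("Om[1]")]
        assert (om >= 0).all() and (om <= priors.om_max).all()
        for blk in ("NY", "NA", "IY", "IA"):
            col = flat[:, tiny_fit.index(f"{blk}[3]")]
            assert (col >= 0).all() and (col == np.round(col)).all()

    def test_same_seed_bit_identical(self, small_bundle):
        cfg = inf.FitConfig(n_chains=2, n_iter=600, n_burnin=200, thin=4,
                            seed=99)
        a = inf.fit_ipm(small_bundle, cfg)
        b = inf.fit_ipm(small_bundle, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_needs_five_years(self, small_bundle):
        import dataclasses
        short = dataclasses.replace(small_bundle, T=3)
        with pytest.raises(ValueError, match="five"):
            inf.fit_ipm(short, inf.FitConfig.test_profile())

    def test_archive_roundtrip(self, tiny_fit, tmp_path):
        tiny_fit.to_dir(tmp_path / "post")
        back = inf.PosteriorSamples.from_dir(tmp_path / "post")
        assert back.names == tiny_fit.names
        np.testing.assert_allclose(back.draws, tiny_fit.draws, rtol=1e-12)
        assert (tmp_path / "post" / "summary.csv").exists()


class TestImputation:
    def test_missing_covariates_become_latent_draws(self, small_dataset,
                                                    tmp_path):
        small_dataset.write(tmp_path)
        import pandas as pd
        w = pd.read_csv(tmp_path / "weather.csv", parse_dates=["date"])
        first_year = w["date"].dt.year.min()
        w = w[w["date"].dt.year != first_year]  # drop one year of weather
        w.to_csv(tmp_path / "weather.csv", index=False)
        data = inf.load_dataset_dir(tmp_path)
        assert data.n_imputed == 3
        cfg = inf.FitConfig(n_chains=2, n_iter=500, n_burnin=200, thin=5,
                            seed=4)
        s = inf.fit_ipm(data, cfg)
        assert np.isfinite(s.draws).all()
        imp = [n for n in s.names if n.startswith("imp_")]
        assert len(imp) == 3
        assert s.get(imp[0]).std() > 0  # the latent covariate actually moves


class TestIndependentFits:
    def test_unsupported_component(self, small_bundle):
        with pytest.raises(ValueError, match="cjs, clutch, nestfate"):
            inf.fit_independent(small_bundle, "counts")

    def test_empty_component_rejected(self, small_bundle):
        import dataclasses
        empty = dataclasses.replace(small_bundle,
                                    ncl=np.zeros_like(small_bundle.ncl))
        with pytest.raises(ValueError, match="clutch"):
            inf.fit_independent(empty, "clutch")

    def test_clutch_alone_recovers_adult_clutch_size(self, small_bundle,
                                                     small_truth):
        cfg = inf.FitConfig(n_chains=2, n_iter=4000, n_burnin=1000, thin=5,
                            seed=11)
        s = inf.fit_independent(small_bundle, "clutch", cfg)
        draws = s.get("CS_A")
        med, sd = np.median(draws), draws.std()
        assert abs(med - small_truth.CS_A) < 2 * max(sd, 0.05)

    def test_cjs_alone_recovers_adult_survival(self, small_bundle,
                                               small_truth):
        cfg = inf.FitConfig(n_chains=2, n_iter=3000, n_burnin=1000, thin=5,
                            seed=12)
        s = inf.fit_independent(small_bundle, "cjs", cfg)
        draws = s.get("sA")
        med, sd = np.median(draws), draws.std()
        assert abs(med - small_truth.sA) < 2 * max(sd, 0.03)


class TestModelChecks:
    def test_predictive_table_shape_and_coverage(self, tiny_fit,
                                                 small_bundle):
        table = inf.posterior_predictive_table(tiny_fit, small_bundle, seed=2)
        T = small_bundle.T
        per_year = table[table["year"] > 0]
        assert len(per_year) == 3 * T + (T - 1)  # newly-ringed skips year 0
        summary = table[table["year"] == -1]
        assert len(summary) == 4
        # the model was fitted to these data, coverage should be high
        assert (summary["covered"] >= 0.8).all()

    def test_projection_table_and_determinism(self, tiny_fit, small_bundle):
        a = inf.forward_projection_check(tiny_fit, small_bundle, horizon=10,
                                         reps=300, seed=6)
        b = inf.forward_projection_check(tiny_fit, small_bundle, horizon=10,
                                         reps=300, seed=6)
        assert len(a) == 10
        assert a.equals(b)
        with pytest.raises(ValueError):
            inf.forward_projection_check(tiny_fit, small_bundle, horizon=0)

    def test_projection_collapses_without_survival(self, tiny_fit,
                                                   small_bundle):
        doctored = inf.PosteriorSamples(
            names=tiny_fit.names, draws=tiny_fit.draws.copy(),
            manifest=tiny_fit.manifest, years=tiny_fit.years,
            config=tiny_fit.config)
        for name in ("sJ", "sA"):
            doctored.draws[:, :, doctored.index(name)] = 1e-9
        off = _mcmc.block_offsets(small_bundle.T)
        for t in range(small_bundle.T):
            doctored.draws[:, :, doctored.index(f"Om[{t}]")] = 0.0
            doctored.draws[:, :, doctored.index(f"eps_sJ[{t}]")] = 0.0
            doctored.draws[:, :, doctored.index(f"eps_sA[{t}]")] = 0.0
        table = inf.forward_projection_check(doctored, small_bundle,
                                             horizon=4, reps=100, seed=1)
        assert (table.loc[table["year_ahead"] >= 1, "upper95"] == 0).all()


def test_more_data_does_not_widen_intervals():
    """Doubling the study length never widens the median credible interval
    of the key rates (checked over replicate pairs)."""
    params = ("sA", "sJ", "CS_A", "pNS")
    widths = {10: {p: [] for p in params}, 20: {p: [] for p in params}}
    cfg = lambda s: inf.FitConfig(n_chains=2, n_iter=1200, n_burnin=400,
                                  thin=4, seed=s)
    import tempfile
    for rep in range(5):
        for T in (10, 20):
            truth = sim.TruthSet(n_years=T, n_boxes=80, init_NY=35,
                                 init_NA=70)
            ds = sim.simulate_dataset(truth, seed=7000 + 13 * rep + T)
            with tempfile.TemporaryDirectory() as d:
                ds.write(d)
                data = inf.load_dataset_dir(d)
            s = inf.fit_ipm(data, cfg(100 + rep))
            for p in params:
                lo, hi = s.ci(p)
                widths[T][p].append(hi - lo)
    for p in params:
        assert np.median(widths[20][p]) <= np.median(widths[10][p])
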