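"""Gibbs sampler full conditionals, posterior summaries and prediction grids."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eggsurf as es
from eggsurf.mixed_model import (ModelSpec, _draw_beta, _draw_species_effects,
                                 _draw_variance, effective_sample_size, hpd,
                                 pmcmc)


def hpd_enumeration_oracle(draws, mass):
    """Enumerate every window of ⌈mass·n⌉ sorted draws; return the shortest."""
    s = np.sort(draws)
    n = s.size
    m = int(np.ceil(mass * n))
    best = None
    for i in range(n - m + 1):
        w = s[i + m - 1] - s[i]
        if best is None or w < best[0]:
            best = (w, s[i], s[i + m - 1])
    return best[1], best[2]


class TestHPD:
    def test_constant_draws(self):
        assert hpd(np.full(10, 3.5), 0.95) == (3.5, 3.5)

    def test_integers_1_to_100(self):
        lo, hi = hpd(np.arange(1.0, 101.0), 0.95)
        assert hi - lo == 94.0
        assert float(hi).is_integer() and float(lo).is_integer()

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        draws = r.gamma(2.0, 1.0, 157)
        for mass in (0.5, 0.8, 0.95):
            assert hpd(draws, mass) == hpd_enumeration_oracle(draws, mass)

    def test_nesting(self, rng):
        draws = rng.standard_normal(400)
        l50, h50 = hpd(draws, 0.5)
        l80, h80 = hpd(draws, 0.8)
        l95, h95 = hpd(draws, 0.95)
        assert l95 <= l80 <= l50 and h50 <= h80 <= h95

    def test_bad_mass(self):
        with pytest.raises(ValueError):
            hpd(np.arange(10.0), 1.5)


class TestPMCMC:
    def test_all_positive_hits_floor(self):
        assert pmcmc(np.abs(np.random.default_rng(0).normal(5, 1, 200))) \
            == pytest.approx(1 / 200)

    def test_symmetric_draws_near_one(self):
        draws = np.concatenate([np.arange(1, 101.0), -np.arange(1, 101.0)])
        assert pmcmc(draws) == 1.0

    def test_normal_tail_oracle(self):
        draws = np.random.default_rng(42).normal(1.0, 1.0, 10000)
        # closed form: 2·Φ(−1) ≈ 0.3173
        assert pmcmc(draws) == pytest.approx(2 * stats.norm.cdf(-1.0), abs=0.02)

    def test_zero_draws(self):
        with pytest.raises(ValueError):
            pmcmc(np.array([]))


class TestFullConditionals:
    """Each Gibbs block against its closed-form conditional moments."""

    def test_beta_conditional_moments(self, rng):
        n, p = 60, 3
        X = rng.standard_normal((n, p))
        target = rng.standard_normal(n)
        s2, v0 = 0.5, 100.0
        prec = X.T @ X / s2 + np.eye(p) / v0
        mean = np.linalg.solve(prec, X.T @ target / s2)
        draws = np.array([_draw_beta(rng, X, target, s2, v0)
                          for _ in range(4000)])
        np.testing.assert_allclose(draws.mean(0), mean, atol=0.05)
        np.testing.assert_allclose(np.cov(draws.T), np.linalg.inv(prec),
                                   atol=0.05)

    def test_species_effect_conditional_moments(self, rng):
        counts = np.array([3.0, 5.0, 2.0])
        sums = np.array([1.5, -2.0, 0.7])
        s2_s, s2_e = 0.8, 0.4
        prec = counts / s2_e + 1 / s2_s
        mean = (sums / s2_e) / prec
        draws = np.array([_draw_species_effects(rng, counts, sums, s2_s, s2_e)
                          for _ in range(6000)])
        np.testing.assert_allclose(draws.mean(0), mean, atol=0.03)
        np.testing.assert_allclose(draws.var(0), 1 / prec, rtol=0.1)

    def test_variance_conditional_is_inverse_gamma(self, rng):
        shape0, scale0, quad, k = 0.001, 0.001, 12.0, 20
        draws = np.array([_draw_variance(rng, shape0, scale0, quad, k)
                          for _ in range(8000)])
        a, b = shape0 + k / 2, scale0 + quad / 2
        ks = stats.kstest(draws, stats.invgamma(a, scale=b).cdf)
        assert ks.pvalue > 0.01


def _study(n_species=30, seed=0, effects=None, **kw):
    tree = es.gen_tree(n_species, seed=seed)
    spec = es.TraitSimSpec(
        n_species=n_species, specimens_per_species=(3, 3),
        fixed_effects=effects if effects is not None
        else {("maculation", "maculate"): 0.5},
        seed=seed + 1, **kw)
    traits, indiv, truth = es.simulate_study(tree, spec)
    data = indiv.merge(traits[["species", "maculation", "body_mass_g"]],
                       on="species")
    return tree, data, truth


class TestFitMCMC:
    SPEC = dict(iterations=1500, burn_in=500, thinning=2, seed=3)

    def test_determinism(self):
        tree, data, _ = _study()
        spec = ModelSpec(response="value", fixed=["maculation"], **self.SPEC)
        s1 = es.fit_mcmc(data, tree, spec)
        s2 = es.fit_mcmc(data, tree, spec)
        np.testing.assert_array_equal(s1.beta, s2.beta)
        np.testing.assert_array_equal(s1.var_phylo, s2.var_phylo)

    def test_recovers_fixed_effect(self):
        tree, data, truth = _study(n_species=60, seed=5)
        spec = ModelSpec(response="value", fixed=["maculation"],
                         iterations=4000, burn_in=1000, thinning=3, seed=7)
        s = es.fit_mcmc(data, tree, spec)
        j = s.beta_names.index("maculation[maculate]")
        lo, hi = hpd(s.beta[:, j], 0.95)
        assert lo <= 0.5 <= hi
        assert s.beta[:, j].mean() == pytest.approx(0.5, abs=0.2)

    def test_unmatched_species_error(self):
        tree, data, _ = _study(n_species=10)
        data.loc[0, "species"] = "NOT_A_TIP"
        spec = ModelSpec(response="value", fixed=[], **self.SPEC)
        with pytest.raises(ValueError, match="NOT_A_TIP"):
            es.fit_mcmc(data, tree, spec)

    def test_draw_count_and_variances_positive(self):
        tree, data, _ = _study(n_species=12)
        spec = ModelSpec(response="value", fixed=["maculation"], **self.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        assert s.n_draws == spec.n_retained
        assert (s.var_phylo > 0).all() and (s.var_species > 0).all() \
            and (s.var_resid > 0).all()

    def test_modelspec_invariants(self):
        with pytest.raises(ValueError, match="100 draws"):
            ModelSpec(response="v", iterations=300, burn_in=200, thinning=10)
        with pytest.raises(ValueError):
            ModelSpec(response="v", iterations=100, burn_in=200)

    def test_ess_reported(self):
        tree, data, _ = _study(n_species=12)
        spec = ModelSpec(response="value", fixed=[], **self.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        assert 1 <= s.ess["(Intercept)"] <= s.n_draws

    def test_ess_agrees_with_arviz(self, rng):
        x = rng.standard_normal(2000)
        # iid draws: ESS near n for both estimators
        assert effective_sample_size(x) > 1200
        arviz = pytest.importorskip("arviz")
        ar = float(arviz.ess(x[None, :]))
        assert effective_sample_size(x) == pytest.approx(ar, rel=0.35)


class TestGridAndPredict:
    def test_grid_row_count(self, rng):
        df = pd.DataFrame({
            "c1": rng.standard_normal(50),
            "c2": rng.standard_normal(50),
            "catA": rng.choice(["x", "y"], 50),
            "catB": rng.choice(["u", "v", "w"], 50),
        })
        grid = es.build_grid(df, ["c1", "c2", "catA", "catB"], bins=3)
        assert len(grid) == 3 * 3 * 2 * 3
        assert grid["c1"].min() == df["c1"].min()
        assert grid["c1"].max() == df["c1"].max()

    def test_grid_categorical_only(self, rng):
        df = pd.DataFrame({"catA": ["a", "b", "a"]})
        assert len(es.build_grid(df, ["catA"])) == 2

    def test_grid_count_formula_random_metadata(self, rng):
        for _ in range(5):
            n_cont = int(rng.integers(0, 3))
            cat_sizes = rng.integers(2, 5, int(rng.integers(0, 3)))
            cols = {}
            for i in range(n_cont):
                cols[f"c{i}"] = rng.standard_normal(30)
            for i, k in enumerate(cat_sizes):
                cols[f"k{i}"] = rng.choice([f"l{j}" for j in range(k)], 30)
            if not cols:
                continue
            df = pd.DataFrame(cols)
            expect = 3 ** n_cont * int(np.prod([df[f"k{i}"].nunique()
                                                for i in range(len(cat_sizes))]))
            assert len(es.build_grid(df, list(cols), bins=3)) == expect

    def test_constant_continuous_warns(self):
        df = pd.DataFrame({"c": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            grid = es.build_grid(df, ["c"])
        assert len(grid) == 1

    def test_batching_invariance_bitwise(self):
        tree, data, _ = _study(n_species=15)
        spec = ModelSpec(response="value", fixed=["maculation", "body_mass_g"],
                         **TestFitMCMC.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        grid = es.build_grid(data, ["maculation", "body_mass_g"])
        p500 = es.posterior_predict(grid, s, batch_size=500).table
        p7 = es.posterior_predict(grid, s, batch_size=7).table
        pd.testing.assert_frame_equal(p500, p7)  # bitwise identical

    def test_intercept_only_prediction(self):
        tree, data, _ = _study(n_species=12)
        spec = ModelSpec(response="value", fixed=[], **TestFitMCMC.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        grid = pd.DataFrame({"dummy": [0]}).drop(columns="dummy", errors="ignore")
        grid = pd.DataFrame(index=[0, 1])
        pred = es.posterior_predict(grid, s, batch_size=1).table
        assert pred["mean"].nunique() == 1
        assert pred["mean"].iloc[0] == pytest.approx(s.beta[:, 0].mean())

    def test_hpd_columns_nested(self):
        tree, data, _ = _study(n_species=12)
        spec = ModelSpec(response="value", fixed=["maculation"],
                         **TestFitMCMC.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        grid = es.build_grid(data, ["maculation"])
        t = es.posterior_predict(grid, s).table
        assert (t["hpd50_low"] >= t["hpd95_low"]).all()
        assert (t["hpd80_high"] <= t["hpd95_high"]).all()

    def test_column_mismatch_error(self):
        tree, data, _ = _study(n_species=12)
        spec = ModelSpec(response="value", fixed=["maculation"],
                         **TestFitMCMC.SPEC)
        s = es.fit_mcmc(data, tree, spec)
        with pytest.raises(ValueError, match="maculation"):
            es.posterior_predict(pd.DataFrame({"diet": ["plant"]}), s)
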