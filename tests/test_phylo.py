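"""Phylogenetic covariance, Pagel's λ, PGLS and the collinearity screen."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import eggsurf as es
from eggsurf.phylo import _gvif, _mvn_profile_loglik, lambda_transform


def star_tree(n, depth=1.0):
    newick = "(" + ",".join(f"T{i}:{depth}" for i in range(n)) + ");"
    return dendropy.Tree.get(data=newick, schema="newick")


def bm_sample(pc, lam, sigma, rng, mu=0.0):
    C = lambda_transform(pc.matrix, lam)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    return mu + sigma * (L @ rng.standard_normal(C.shape[0]))


class TestVCV:
    def test_hand_computed_example(self, small_tree):
        pc = es.vcv(small_tree, taxa=["A", "B", "C"])
        expect = np.array([[2.0, 1.0, 0.0],
                           [1.0, 2.0, 0.0],
                           [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(pc.matrix, expect)

    def test_star_tree_is_diagonal(self):
        pc = es.vcv(star_tree(6))
        np.testing.assert_allclose(pc.matrix, np.eye(6))

    def test_tip_permutation_consistency(self):
        tree = es.gen_tree(12, seed=4)
        pc = es.vcv(tree)
        perm = list(reversed(pc.taxa))
        pc2 = es.vcv(tree, taxa=perm)
        idx = [pc.taxa.index(t) for t in perm]
        np.testing.assert_allclose(pc2.matrix, pc.matrix[np.ix_(idx, idx)])

    def test_normalization(self):
        tree = es.gen_tree(10, seed=2)
        pc = es.vcv(tree, normalize=True)
        assert np.diag(pc.matrix).max() == pytest.approx(1.0)
        assert pc.depth_scale > 0

    def test_psd_and_row_dominance(self):
        pc = es.vcv(es.gen_tree(25, seed=9))
        eig = np.linalg.eigvalsh(pc.matrix)
        assert eig.min() > -1e-10
        d = np.diag(pc.matrix)
        assert (pc.matrix <= d[:, None] + 1e-12).all()

    def test_lambda_transform(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        out = lambda_transform(C, 0.5)
        np.testing.assert_allclose(out, [[2.0, 0.5], [0.5, 2.0]])


class TestFitLambda:
    def test_optimizer_beats_dense_grid(self):
        rng = np.random.default_rng(21)
        pc = es.vcv(es.gen_tree(50, seed=3), normalize=True)
        for _ in range(3):
            y = bm_sample(pc, 0.7, 1.0, rng)
            fit = es.fit_lambda(y, pc)
            grid = np.linspace(0, 1, 1001)
            grid_ll = max(_mvn_profile_loglik(
                y, lambda_transform(pc.matrix, g))[0] for g in grid)
            assert fit.loglik >= grid_ll - 1e-6

    def test_loglik_at_estimate_dominates_boundaries(self):
        rng = np.random.default_rng(8)
        pc = es.vcv(es.gen_tree(40, seed=1), normalize=True)
        y = bm_sample(pc, 0.5, 1.0, rng)
        fit = es.fit_lambda(y, pc)
        assert fit.loglik >= max(fit.loglik0, fit.loglik1) - 1e-9
        assert 0 <= fit.p_lambda0 <= 1 and 0 <= fit.p_lambda1 <= 1

    def test_bm_signal_detected(self):
        rng = np.random.default_rng(17)
        pc = es.vcv(es.gen_tree(120, seed=5), normalize=True)
        y = bm_sample(pc, 1.0, 1.0, rng)
        fit = es.fit_lambda(y, pc)
        assert fit.lam > 0.8
        assert fit.p_lambda0 < 0.05

    def test_iid_data_has_no_signal(self):
        rng = np.random.default_rng(18)
        pc = es.vcv(es.gen_tree(120, seed=5), normalize=True)
        y = rng.standard_normal(120)
        fit = es.fit_lambda(y, pc)
        assert fit.lam < 0.3
        assert fit.p_lambda1 < 0.05

    def test_star_tree_flat_likelihood_flagged(self):
        rng = np.random.default_rng(19)
        pc = es.vcv(star_tree(30))
        fit = es.fit_lambda(rng.standard_normal(30), pc)
        assert fit.flat_likelihood

    def test_small_sample_refused(self):
        pc = es.vcv(star_tree(3))
        with pytest.raises(ValueError):
            es.fit_lambda(np.array([1.0, 2.0, 3.0]), pc)


class TestPGLS:
    def test_identity_reduces_to_ols_exactly(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal(n),
                             rng.standard_normal(n)])
        y = X @ [1.0, 2.0, -0.5] + rng.standard_normal(n)
        pc = es.vcv(es.gen_tree(n, seed=2), normalize=True)
        fit = es.pgls(y, X, pc, correlation="identity")
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.params, ols.params, atol=1e-12)
        np.testing.assert_allclose(fit.bse, ols.bse, atol=1e-12)
        np.testing.assert_allclose(fit.pvalues, ols.pvalues, atol=1e-12)
        assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-12)

    def test_slope_recovery_under_phylo_noise(self):
        rng = np.random.default_rng(30)
        pc = es.vcv(es.gen_tree(150, seed=6), normalize=True)
        hits = 0
        for _ in range(20):
            x = rng.standard_normal(150)
            y = 2.0 + 3.0 * x + bm_sample(pc, 1.0, 0.8, rng)
            fit = es.pgls(y, np.column_stack([np.ones(150), x]), pc)
            lo = fit.params[1] - 1.96 * fit.bse[1]
            hi = fit.params[1] + 1.96 * fit.bse[1]
            hits += lo <= 3.0 <= hi
        assert hits >= 16  # ~95% nominal coverage over 20 replicates

    def test_duplicated_column_aliasing_error(self, rng):
        n = 20
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x])
        pc = es.vcv(es.gen_tree(n, seed=3), normalize=True)
        with pytest.raises(ValueError, match="aliased"):
            es.pgls(rng.standard_normal(n), X, pc, names=["int", "x", "x_copy"])

    def test_lambda_estimated_matches_fixed_at_optimum(self):
        rng = np.random.default_rng(31)
        pc = es.vcv(es.gen_tree(60, seed=7), normalize=True)
        x = rng.standard_normal(60)
        y = 1.0 + 0.5 * x + bm_sample(pc, 0.6, 0.5, rng)
        X = np.column_stack([np.ones(60), x])
        est = es.pgls(y, X, pc, correlation="lambda-estimated")
        fixed = es.pgls(y, X, pc, correlation="lambda-fixed", lam=est.lam)
        np.testing.assert_allclose(est.params, fixed.params, rtol=1e-8)


class TestCollinearityScreen:
    def test_duplicate_variable_one_dropped(self, rng):
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        rep = es.collinearity_screen(df)
        assert len(rep.retained) == 2 and "c" in rep.retained
        assert rep.dropped[0]["pass"] == "pairwise-r"

    def test_orthogonal_predictors_all_retained(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((60, 4)))
        df = pd.DataFrame(q, columns=list("abcd"))
        rep = es.collinearity_screen(df)
        assert rep.retained == list("abcd") and not rep.dropped

    def test_linear_combination_caught_by_vif(self, rng):
        x1 = rng.standard_normal(80)
        x2 = rng.standard_normal(80)
        x3 = 0.5 * x1 + 0.5 * x2 + 0.02 * rng.standard_normal(80)
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        rep = es.collinearity_screen(df, r_max=0.9)
        assert len(rep.retained) == 2
        assert any(d["pass"] == "vif" for d in rep.dropped)

    def test_constant_predictor_warned_and_dropped(self, rng):
        df = pd.DataFrame({"k": np.ones(30), "x": rng.standard_normal(30),
                           "y": rng.standard_normal(30)})
        with pytest.warns(UserWarning, match="constant"):
            rep = es.collinearity_screen(df)
        assert "k" not in rep.retained

    def test_gvif_matches_regression_vif_oracle(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 2] = 0.7 * X[:, 0] + rng.standard_normal(100) * 0.5
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        R = df.corr().to_numpy()
        for j, name in enumerate(df.columns):
            others = [c for c in df.columns if c != name]
            r2 = sm.OLS(df[name], sm.add_constant(df[others])).fit().rsquared
            assert _gvif(R, np.array([j])) == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_categorical_predictors_screenable(self, rng):
        df = pd.DataFrame({
            "maculation": rng.choice(["maculate", "immaculate"], 60),
            "mass": rng.standard_normal(60),
        })
        # a perfect copy of a categorical must be dropped
        df["maculation2"] = df["maculation"]
        rep = es.collinearity_screen(df)
        assert len(rep.retained) == 2
        assert sum(p in rep.retained
                   for p in ("maculation", "maculation2")) == 1
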