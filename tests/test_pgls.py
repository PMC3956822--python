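"""GLS likelihood, λ estimation and the classic equivalences.

The two anchor identities: PGLS with λ=0 on an ultrametric tree is ordinary
least squares on the raw data, and PGLS with λ=1 reproduces the
independent-contrasts regression-through-origin slope.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import phylofid as pf
from phylofid.pgls import PGLS, CollinearityError, SingularCovarianceError

from oracles import dense_gls_loglik, pic_regression_slope


def _sim_xy(cov, rng, lam=1.0):
    x = pf.simulate_trait(cov, lam, 1.0, 0.0, rng)
    y = 0.7 * x + pf.simulate_trait(cov, lam, 0.5, 0.0, rng)
    return x, y


class TestLoglik:
    def test_matches_dense_inverse_oracle_on_6_tip_trees(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            tree = pf.simulate_tree(6, seed=seed)
            cov = tree.vcv()
            y = rng.normal(size=6)
            X = rng.normal(size=(6, 2))
            model = PGLS(y, X, cov)
            Xi = np.column_stack([np.ones(6), X])
            for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
                V = cov.lambda_transform(lam).matrix
                assert model.loglike(lam) == pytest.approx(
                    dense_gls_loglik(y, Xi, V), abs=1e-8)

    def test_lambda0_intercept_only_is_iid_normal_loglik(self):
        # on an ultrametric tree the variance rescaling by tip depth cancels
        # against the determinant term, leaving the i.i.d. normal ML value
        tree = pf.simulate_tree(16, seed=2)
        cov = tree.vcv()
        rng = np.random.default_rng(3)
        y = rng.normal(2.0, 1.0, 16)
        ll = PGLS(y, None, cov).loglike(0.0)
        iid = -0.5 * (16 * np.log(2 * np.pi * np.var(y)) + 16)
        assert ll == pytest.approx(iid, abs=1e-8)

    def test_singular_covariance_names_taxa_pair(self):
        # zero-length cherry: two tips with identical covariance rows
        t = pf.Phylogeny.from_string("((A:0,B:0):1,C:1);")
        with pytest.raises(SingularCovarianceError, match="'A' and 'B'"):
            PGLS(np.arange(3.0), None, t.vcv()).loglike(1.0)

    def test_collinear_predictors_rejected(self, yule24_cov, rng):
        x = rng.normal(size=24)
        with pytest.raises(CollinearityError):
            PGLS(rng.normal(size=24), np.column_stack([x, 2 * x]),
                 yule24_cov).fit(lambda_mode="fixed0")


class TestEquivalences:
    def test_lambda0_equals_ols(self, yule24, rng):
        cov = yule24.vcv()
        X = rng.normal(size=(24, 2))
        y = 1.0 + X @ [0.5, -0.3] + rng.normal(size=24)
        fit = PGLS(y, X, cov).fit(lambda_mode="fixed0")
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params, atol=1e-8)
        assert np.allclose(fit.bse.to_numpy(), ols.bse, atol=1e-8)
        assert fit.rsquared == pytest.approx(ols.rsquared, abs=1e-8)

    @pytest.mark.parametrize("seed", range(50))
    def test_lambda1_slope_equals_independent_contrasts(self, seed):
        rng = np.random.default_rng(seed)
        tree = pf.simulate_tree(15, seed=seed)
        cov = tree.vcv()
        x, y = _sim_xy(cov, rng)
        fit = PGLS(y, x, cov).fit(lambda_mode="fixed1")
        slope = pic_regression_slope(tree, dict(zip(cov.taxa, x)),
                                     dict(zip(cov.taxa, y)))
        assert fit.params.iloc[1] == pytest.approx(slope, abs=1e-8)


class TestLambdaEstimation:
    def test_profile_maximality_on_grid(self, yule24_cov, rng):
        y = pf.simulate_trait(yule24_cov, 0.6, 1.0, 0.0, rng)
        model = PGLS(y, None, yule24_cov)
        est = model.estimate_lambda()
        grid = np.linspace(0, 1, 101)
        assert est.loglik_at_hat >= max(model.loglike(l) for l in grid) - 1e-6

    def test_estimate_invariants(self, yule24_cov, rng):
        y = pf.simulate_trait(yule24_cov, 0.5, 1.0, 0.0, rng)
        est = pf.estimate_lambda(y, yule24_cov)
        assert 0.0 <= est.lambda_hat <= 1.0
        assert est.loglik_at_hat >= max(est.loglik_at_0, est.loglik_at_1) - 1e-6
        assert 0.0 <= est.p_vs_0 <= 1.0 and 0.0 <= est.p_vs_1 <= 1.0

    def test_iid_data_on_star_phylogeny_gives_zero(self, rng):
        # star: no internal branches, so no signal is even expressible;
        # on a real tree i.i.d. data should still drive lambda to 0
        tree = pf.simulate_tree(48, seed=13)
        y = rng.normal(size=48)
        est = pf.estimate_lambda(y, tree.vcv())
        assert est.lambda_hat < 0.05

    def test_brownian_trait_recovers_high_lambda(self, rng):
        tree = pf.simulate_tree(96, seed=17)
        cov = tree.vcv()
        hats = [pf.estimate_lambda(
            pf.simulate_trait(cov, 1.0, 1.0, 0.0, rng), cov).lambda_hat
            for _ in range(20)]
        assert np.mean(hats) > 0.9

    def test_brownian_likelihood_prefers_lambda1_over_0(self, rng):
        tree = pf.simulate_tree(128, seed=23)
        cov = tree.vcv()
        wins = 0
        for _ in range(25):
            y = pf.simulate_trait(cov, 1.0, 1.0, 0.0, rng)
            m = PGLS(y, None, cov)
            wins += m.loglike(1.0) > m.loglike(0.0)
        assert wins == 25

    def test_boundary_mixture_halves_pvalue(self, yule24_cov, rng):
        y = pf.simulate_trait(yule24_cov, 0.8, 1.0, 0.0, rng)
        plain = pf.estimate_lambda(y, yule24_cov)
        mixed = pf.estimate_lambda(y, yule24_cov, boundary_mixture=True)
        if 0.0 < plain.p_vs_0 < 1.0:
            assert mixed.p_vs_0 == pytest.approx(plain.p_vs_0 / 2)


class TestResultsObject:
    def test_fit_modes_and_k_params(self, yule24_cov, rng):
        y = pf.simulate_trait(yule24_cov, 0.5, 1.0, 0.0, rng)
        x = rng.normal(size=24)
        model = PGLS(y, x, yule24_cov)
        ml = model.fit("ml")
        f0 = model.fit("fixed0")
        fv = model.fit("fixed_value", lambda_value=0.3)
        assert ml.k_params == f0.k_params + 1 == 4
        assert fv.lambda_ == 0.3
        with pytest.raises(ValueError):
            model.fit("fixed_value")
        with pytest.raises(ValueError):
            model.fit("nonsense")

    def test_residuals_on_observation_scale(self, yule24_cov, rng):
        x = rng.normal(size=24)
        y = 2.0 + 0.5 * x + rng.normal(size=24)
        fit = PGLS(y, x, yule24_cov).fit("fixed1")
        assert np.allclose(fit.resid.to_numpy(),
                           y - fit.fittedvalues.to_numpy())

    def test_from_dataframe_aligns_covariance(self, yule24_cov, rng):
        df = pd.DataFrame({"y": rng.normal(size=24),
                           "x": rng.normal(size=24)},
                          index=yule24_cov.taxa)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = PGLS.from_dataframe(df, "y", ["x"], yule24_cov).fit("fixed1")
        b = PGLS.from_dataframe(shuffled, "y", ["x"], yule24_cov).fit("fixed1")
        assert np.allclose(a.params.to_numpy(), b.params.to_numpy())

    def test_formula_interface(self, yule24_cov, rng):
        df = pd.DataFrame({"y": rng.normal(size=24),
                           "x": rng.normal(size=24)},
                          index=yule24_cov.taxa)
        f = PGLS.from_formula("y ~ x", df, yule24_cov).fit("fixed0")
        g = PGLS.from_dataframe(df, "y", ["x"], yule24_cov).fit("fixed0")
        assert np.allclose(f.params.to_numpy(), g.params.to_numpy())
        assert PGLS.from_formula("y ~ 1", df, yule24_cov).exog.shape[1] == 1

    def test_summary_mentions_lambda_and_coefficients(self, yule24_cov, rng):
        fit = PGLS(rng.normal(size=24), rng.normal(size=24),
                   yule24_cov, exog_names=["mass"]).fit("ml")
        text = fit.summary()
        assert "lambda" in text and "mass" in text


class TestAicc:
    def test_formula_and_large_n_limit(self):
        ll, k = -10.0, 3
        assert pf.aicc(ll, k, 100) == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (100 - k - 1))
        assert pf.aicc(ll, k, 10**9) == pytest.approx(-2 * ll + 2 * k, abs=1e-6)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            pf.aicc(-10.0, 3, 4)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(lam=st.floats(0.0, 1.0), seed=st.integers(0, 10**6))
def test_lambda_transform_preserves_symmetry_and_diagonal(lam, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(6, 6))
    C = pf.PhyloCovariance([f"t{i}" for i in range(6)], A @ A.T)
    T = C.lambda_transform(lam)
    assert np.allclose(T.matrix, T.matrix.T)
    assert np.allclose(np.diag(T.matrix), np.diag(C.matrix))
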