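"""PGLS: design matrices, GLS fitting, lambda profiling, AIC comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import richrates as rr
from richrates.pgls import SUBSTANTIAL_DELTA_AIC, build_design, parse_formula

from oracles import gls_beta_explicit


def _toy_frame(n=15, seed=0, taxa=None):
    gen = np.random.default_rng(seed)
    idx = taxa if taxa is not None else [f"t{i+1}" for i in range(n)]
    return pd.DataFrame(
        {
            "y": gen.normal(size=n),
            "a": gen.normal(size=n),
            "b": gen.normal(size=n),
        },
        index=idx,
    )


class TestDesign:
    def test_single_term(self, clade_table):
        d = build_design(clade_table.data, "ln_richness", ["climate_rate"])
        assert d.X.shape == (15, 2)
        assert d.term_names == ("Intercept", "climate_rate")
        assert np.allclose(d.X[:, 0], 1.0)

    def test_interaction_pulls_in_main_effects(self, clade_table):
        d = build_design(
            clade_table.data, "gamma", ["crown_age"],
            interactions=[("crown_age", "size_rate")],
        )
        assert d.X.shape[1] == 4  # intercept, age, size rate, product
        col = dict(zip(d.term_names, d.X.T))
        assert np.allclose(
            col["crown_age:size_rate"], col["crown_age"] * col["size_rate"]
        )

    def test_self_interaction_rejected(self, clade_table):
        with pytest.raises(ValueError, match="itself"):
            build_design(clade_table.data, "gamma", interactions=[("crown_age", "crown_age")])

    def test_collinear_columns_named(self):
        df = _toy_frame()
        df["a2"] = 2.0 * df["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(df, "y", ["a", "a2"])

    def test_missing_column_rejected(self, clade_table):
        with pytest.raises(KeyError):
            build_design(clade_table.data, "ln_richness", ["not_a_column"])

    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("y ~ a", ("y", ["a"], [])),
            ("y ~ 1", ("y", [], [])),
            ("y ~ a + b + a:b", ("y", ["a", "b"], [("a", "b")])),
            ("y ~ a*b", ("y", [], [("a", "b")])),
        ],
    )
    def test_parse_formula(self, formula, expected):
        assert parse_formula(formula) == expected

    def test_parse_formula_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_formula("y ~ a ~ b")


class TestGLSFit:
    def test_lambda_zero_on_ultrametric_tree_equals_ols(self):
        # with lambda = 0 the covariance is a scaled identity -> OLS
        tree = rr.simulate_yule(15, 0.2, seed=3)
        df = _toy_frame(taxa=tree.tip_labels, seed=3)
        res = rr.PGLS.from_formula("y ~ a + b", df, tree.vcv()).fit(lam=0.0)
        ols = sm.OLS(df["y"], sm.add_constant(df[["a", "b"]])).fit()
        assert np.allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-10)
        assert res.rsquared == pytest.approx(ols.rsquared, abs=1e-10)
        assert res.fvalue == pytest.approx(ols.fvalue, abs=1e-8)
        assert res.f_pvalue == pytest.approx(ols.f_pvalue, abs=1e-10)
        assert np.allclose(res.bse.to_numpy(), ols.bse.to_numpy(), atol=1e-10)

    def test_identity_covariance_reproduces_ols(self, rng):
        n = 12
        df = _toy_frame(n=n, seed=8)
        res = rr.PGLS.from_formula("y ~ a", df, np.eye(n)).fit(lam=1.0)
        ols = sm.OLS(df["y"], sm.add_constant(df["a"])).fit()
        assert np.allclose(res.params.to_numpy(), ols.params.to_numpy(), atol=1e-10)
        assert res.rsquared == pytest.approx(ols.rsquared, abs=1e-10)

    def test_exact_linear_relation_recovered(self):
        tree = rr.simulate_yule(4, 1.0, seed=1)
        df = pd.DataFrame(index=tree.tip_labels)
        df["x"] = [0.0, 1.0, 2.0, 3.0]
        df["y"] = 2.0 * df["x"]
        res = rr.PGLS.from_formula("y ~ x", df, tree.vcv()).fit(lam=1.0)
        assert res.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_three_tip_closed_form_beta(self, three_tip_tree, rng):
        C = three_tip_tree.vcv()
        y = rng.normal(size=3)
        X = np.column_stack([np.ones(3), rng.normal(size=3)])
        res = rr.PGLS.from_arrays(y, X, C, taxa=C.taxa).fit(lam=1.0)
        expected = gls_beta_explicit(y, X, C.matrix)
        assert np.allclose(res.params.to_numpy(), expected, atol=1e-12)

    def test_insufficient_data_rejected(self, three_tip_tree):
        C = three_tip_tree.vcv()
        y = np.arange(3.0)
        X = np.column_stack([np.ones(3), np.arange(3.0), np.arange(3.0) ** 2])
        with pytest.raises(ValueError, match="insufficient"):
            rr.PGLS.from_arrays(y, X, C, taxa=C.taxa)

    def test_r2_invariant_beta_contravariant_to_predictor_rescaling(self):
        tree = rr.simulate_yule(15, 0.3, seed=9)
        df = _toy_frame(taxa=tree.tip_labels, seed=9)
        C = tree.vcv()
        base = rr.PGLS.from_formula("y ~ a", df, C).fit(lam=1.0)
        df2 = df.assign(a=3.0 * df["a"] + 5.0)
        scaled = rr.PGLS.from_formula("y ~ a", df2, C).fit(lam=1.0)
        assert scaled.rsquared == pytest.approx(base.rsquared, abs=1e-10)
        assert scaled.params["a"] == pytest.approx(base.params["a"] / 3.0, abs=1e-10)

    def test_aic_identity_and_lambda_parameter_counting(self, clade_table, backbone_tree):
        m = rr.PGLS.from_formula(
            "ln_richness ~ climate_rate", clade_table.data, backbone_tree.vcv()
        )
        res = m.fit()
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params, abs=1e-12)
        res_no_lam = m.fit(count_lambda_in_k=False)
        assert res_no_lam.k_params == res.k_params - 1
        fixed = m.fit(lam=res.lambda_)
        assert fixed.k_params == 3  # two coefficients + residual variance


class TestProfileLambda:
    def test_profile_likelihood_optimality_on_grid(self, clade_table, backbone_tree):
        m = rr.PGLS.from_formula(
            "ln_richness ~ climate_rate", clade_table.data, backbone_tree.vcv()
        )
        res = m.fit()
        grid = np.arange(0.0, 1.0001, 0.05)
        grid_best = max(m.loglike(max(l, 1e-7)) for l in grid)
        assert res.llf >= grid_best - 1e-6

    def test_star_tree_flagged_uninformative(self, star4_tree):
        df = _toy_frame(n=4, taxa=star4_tree.tip_labels)
        res = rr.PGLS.from_formula("y ~ a", df, star4_tree.vcv()).fit()
        assert "uninformative" in res.lambda_flags

    def test_recovers_high_lambda_from_phylogenetic_data(self):
        rng = np.random.default_rng(2)
        lams = []
        for _ in range(15):
            tree = rr.simulate_yule(200, 0.5, rng)
            C = tree.vcv()
            y = rr.simulate_bm(C, 0.3, rng).iloc[:, 0]
            res = rr.PGLS.from_arrays(
                y.to_numpy(), np.ones((200, 1)), C, taxa=C.taxa
            ).fit()
            lams.append(res.lambda_)
        assert np.median(lams) >= 0.9

    def test_near_zero_lambda_for_independent_noise(self):
        rng = np.random.default_rng(4)
        lams = []
        for _ in range(15):
            tree = rr.simulate_yule(100, 0.5, rng)
            C = tree.vcv()
            y = rng.standard_normal(100)
            res = rr.PGLS.from_arrays(
                y, np.ones((100, 1)), C, taxa=C.taxa
            ).fit()
            lams.append(res.lambda_)
        assert np.median(lams) <= 0.1

    def test_summary_mentions_lambda_and_model(self, clade_table, backbone_tree):
        res = rr.PGLS.from_formula(
            "ln_richness ~ climate_rate", clade_table.data, backbone_tree.vcv()
        ).fit()
        text = res.summary()
        assert "lambda" in text and "climate_rate" in text and "AIC" in text


class TestModelComparison:
    @staticmethod
    def _fits_with_aic(aics, response="y"):
        tree = rr.simulate_yule(10, 0.5, seed=6)
        df = _toy_frame(n=10, taxa=tree.tip_labels, seed=6)
        fits = []
        for target in aics:
            f = rr.PGLS.from_formula(f"{response} ~ a", df, tree.vcv()).fit(lam=1.0)
            f.aic = target  # ranking logic only depends on the AIC values
            fits.append(f)
        return fits

    def test_reported_pair_not_substantially_different(self):
        comp = rr.compare_models(self._fits_with_aic([15.04822, 18.26653]), ["full", "climate"])
        assert comp.delta("climate", "full") == pytest.approx(3.21831, abs=1e-5)
        assert not comp.substantially_better("full", "climate")
        assert not bool(comp.table.loc["climate", "substantially_worse"])

    def test_identical_aics(self):
        comp = rr.compare_models(self._fits_with_aic([10.0, 10.0]), ["m1", "m2"])
        assert np.allclose(comp.table["dAIC"], 0.0)
        assert not comp.table["substantially_worse"].any()

    def test_boundary_difference_of_four_is_substantial(self):
        comp = rr.compare_models(self._fits_with_aic([10.0, 14.0]), ["m1", "m2"])
        assert bool(comp.table.loc["m2", "substantially_worse"])
        assert comp.substantially_better("m1", "m2")
        assert SUBSTANTIAL_DELTA_AIC == 4.0

    def test_mixed_responses_rejected(self):
        tree = rr.simulate_yule(10, 0.5, seed=6)
        df = _toy_frame(n=10, taxa=tree.tip_labels, seed=6)
        f1 = rr.PGLS.from_formula("y ~ a", df, tree.vcv()).fit(lam=1.0)
        f2 = rr.PGLS.from_formula("a ~ b", df, tree.vcv()).fit(lam=1.0)
        with pytest.raises(ValueError, match="mixed responses"):
            rr.compare_models([f1, f2])
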