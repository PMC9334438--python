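import numpy as np
import pandas as pd
import pytest
import scipy.stats
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit

import statsmodels.api as sm

from vocalid.mixed import (
    BinomialMixedModel,
    LinearMixedModel,
    backwards_eliminate,
    odds_ratio,
    wilcoxon_signed_rank,
)


def make_gaussian(rng, n_groups=28, n_per=10, re_sd=5.0, resid=25.0):
    g = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=n_groups * n_per)
    u = rng.normal(0, re_sd, n_groups)
    y = 50 + 3.0 * x + u[g] + rng.normal(0, resid, n_groups * n_per)
    X = pd.DataFrame({"Intercept": 1.0, "x": x})
    return X, y, g


class TestLinearMixedModel:
    def test_noiseless_linear_data_fit_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        y = 2.0 + 3.5 * x
        res = LinearMixedModel(X, y, {}).fit()
        assert res.params["Intercept"] == pytest.approx(2.0, abs=1e-8)
        assert res.params["x"] == pytest.approx(3.5, abs=1e-8)

    def test_agrees_with_statsmodels_mixedlm(self):
        rng = np.random.default_rng(1)
        X, y, g = make_gaussian(rng)
        mine = LinearMixedModel(X, y, {"dog": g}).fit()
        ref = sm.MixedLM(y, X.values, groups=g).fit(reml=True)
        assert np.allclose(mine.params.to_numpy(), ref.params[:2], atol=1e-4)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert mine.vcomp["dog"] == pytest.approx(float(np.squeeze(ref.cov_re)), rel=1e-3)
        assert mine.sigma2 == pytest.approx(ref.scale, rel=1e-3)

    def test_satterthwaite_df_within_sane_range(self):
        rng = np.random.default_rng(2)
        X, y, g = make_gaussian(rng)
        res = LinearMixedModel(X, y, {"dog": g}).fit()
        # the within-group slope has near-residual df; none exceed n - p
        assert 1 <= res.df["Intercept"] <= 278
        assert res.df["Intercept"] < res.df["x"]

    def test_invariant_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(3)
        X, y, g = make_gaussian(rng, n_groups=10)
        base = LinearMixedModel(X, y, {"dog": g}).fit()
        perm = rng.permutation(len(y))
        relabeled = np.array([f"dog{v}" for v in g])
        shuf = LinearMixedModel(X.iloc[perm], y[perm], {"dog": relabeled[perm]}).fit()
        assert np.allclose(base.params.to_numpy(), shuf.params.to_numpy(), atol=1e-4)
        assert base.vcomp["dog"] == pytest.approx(shuf.vcomp["dog"], rel=1e-3)

    def test_zero_variance_factor_dropped(self):
        # no true dog or speaker effect: boundary estimates are pruned
        rng = np.random.default_rng(10)
        g = np.repeat(np.arange(15), 12)
        x = rng.normal(size=len(g))
        y = 50 + 3.0 * x + rng.normal(0, 10.0, len(g))
        spk = rng.integers(0, 8, len(y))
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        res = LinearMixedModel(X, y, {"dog": g, "speaker": spk}).fit(
            drop_zero_variance=True
        )
        assert set(res.dropped_factors) == {"dog", "speaker"}
        assert res.vcomp == {}

    def test_contrast_combines_coefficients(self):
        rng = np.random.default_rng(5)
        X, y, g = make_gaussian(rng)
        X["z"] = rng.normal(size=len(y))
        model = LinearMixedModel(X, y, {"dog": g})
        res = model.fit()
        c = model.contrast(res, {"x": 1.0, "z": 1.0})
        assert c["estimate"] == pytest.approx(res.params["x"] + res.params["z"])
        var = (
            res.cov_params[1, 1] + res.cov_params[2, 2] + 2 * res.cov_params[1, 2]
        )
        assert c["se"] == pytest.approx(np.sqrt(var))


class TestBinomialMixedModel:
    def test_sigma_zero_matches_closed_form_logit(self):
        rng = np.random.default_rng(6)
        y = rng.binomial(1, 0.8, 300).astype(float)
        g = np.repeat(np.arange(30), 10)
        res = BinomialMixedModel(
            pd.DataFrame({"Intercept": np.ones(300)}), y, {"dog": g}
        ).fit(drop_zero_variance=False)
        expected = np.log(y.mean() / (1 - y.mean()))
        assert res.params["Intercept"] == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_brute_force_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        n_g, n_p = 28, 10
        g = np.repeat(np.arange(n_g), n_p)
        x = rng.integers(0, 2, n_g * n_p).astype(float)
        u = rng.normal(0, 1.0, n_g)
        y = rng.binomial(1, expit(1.6 + 0.7 * x + u[g])).astype(float)
        X = pd.DataFrame({"Intercept": 1.0, "x": x})
        mine = BinomialMixedModel(X, y, {"dog": g}).fit(drop_zero_variance=False)

        # independent oracle: fixed-grid 80-node GH likelihood + Nelder-Mead
        xg, wg = hermgauss(80)

        def negll(p):
            b0, b1, logs = p
            s = np.exp(logs)
            eta0 = b0 + b1 * x
            tot = 0.0
            for d in range(n_g):
                m = g == d
                e = eta0[m][None, :] + np.sqrt(2) * s * xg[:, None]
                ll = (y[m][None, :] * e - np.logaddexp(0, e)).sum(axis=1)
                mx = ll.max()
                tot += np.log(np.sum(wg * np.exp(ll - mx))) + mx - 0.5 * np.log(np.pi)
            return -tot

        ref = minimize(
            negll, [1.0, 0.5, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        assert np.allclose(mine.params.to_numpy(), ref.x[:2], atol=2e-3)
        assert np.sqrt(mine.vcomp["dog"]) == pytest.approx(np.exp(ref.x[2]), abs=2e-3)
        assert -mine.loglik == pytest.approx(ref.fun, abs=1e-4)

    def test_odds_ratio_identity_for_every_term(self):
        rng = np.random.default_rng(8)
        g = np.repeat(np.arange(20), 8)
        x = rng.normal(size=160)
        y = rng.binomial(1, expit(0.5 + x)).astype(float)
        res = BinomialMixedModel(
            pd.DataFrame({"Intercept": 1.0, "x": x}), y, {"dog": g}
        ).fit()
        ors = res.odds_ratios()
        for name in res.names:
            assert ors[name] == pytest.approx(np.exp(res.params[name]), abs=1e-12)

    def test_near_separation_stays_finite(self):
        g = np.repeat(np.arange(20), 10)
        y = np.ones(200)
        y[::10] = 0.0  # one incorrect trial per dog
        res = BinomialMixedModel(
            pd.DataFrame({"Intercept": np.ones(200)}), y, {"dog": g}
        ).fit()
        assert np.isfinite(res.params["Intercept"])
        assert res.params["Intercept"] > 0

    def test_crossed_factors_recover_both_variances(self):
        rng = np.random.default_rng(9)
        n_g, n_p = 40, 12
        dog = np.repeat(np.arange(n_g), n_p)
        spk = rng.integers(0, 14, n_g * n_p)
        u = rng.normal(0, 1.2, n_g)
        v = rng.normal(0, 0.8, 14)
        y = rng.binomial(1, expit(0.5 + u[dog] + v[spk])).astype(float)
        res = BinomialMixedModel(
            pd.DataFrame({"Intercept": np.ones(len(y))}), y,
            {"dog": dog, "speaker": spk},
        ).fit(drop_zero_variance=False)
        assert res.method == "Laplace"
        assert 0.3 < res.vcomp["dog"] < 4.0
        assert 0.05 < res.vcomp["speaker"] < 3.0

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            BinomialMixedModel(
                pd.DataFrame({"Intercept": np.ones(4)}),
                np.array([0.0, 0.5, 1.0, 1.0]),
                {"g": np.array([0, 0, 1, 1])},
            )


class TestBackwardsElimination:
    def fit_builder(self, X_all, y, g):
        def build(terms):
            X = X_all[["Intercept"] + list(terms)]
            return LinearMixedModel(X, y, {"dog": g}).fit()

        return build

    def test_strong_term_always_retained(self):
        rng = np.random.default_rng(10)
        g = np.repeat(np.arange(20), 10)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        X.insert(0, "Intercept", 1.0)
        y = 10 + 5.0 * X["a"] + rng.normal(0, 1, 200)  # |t| >> 5 for a
        fit, log = backwards_eliminate(self.fit_builder(X, y, g), ["a", "b", "c"])
        assert "a" in fit.names
        assert {e["term"] for e in log} <= {"b", "c"}

    def test_empty_candidates_returns_intercept_only(self):
        rng = np.random.default_rng(11)
        g = np.repeat(np.arange(10), 10)
        X = pd.DataFrame({"Intercept": np.ones(100)})
        y = rng.normal(5, 1, 100)
        fit, log = backwards_eliminate(self.fit_builder(X, y, g), [])
        assert fit.names == ["Intercept"]
        assert log == []

    def test_interactions_removed_before_main_effects(self):
        rng = np.random.default_rng(12)
        g = np.repeat(np.arange(20), 10)
        a, b = rng.normal(size=(2, 200))
        X = pd.DataFrame({"Intercept": 1.0, "a": a, "b": b, "a:b": a * b})
        y = rng.normal(size=200)  # everything null
        fit, log = backwards_eliminate(self.fit_builder(X, y, g), ["a", "b", "a:b"])
        removed = [e["term"] for e in log]
        if "a" in removed and "a:b" in removed:
            assert removed.index("a:b") < removed.index("a")


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        assert wilcoxon_signed_rank(np.zeros(23)) == (0.0, 1.0)
        x = np.array([0.8, 0.9, 0.7])
        assert wilcoxon_signed_rank(x, x.copy()) == (0.0, 1.0)

    def test_antisymmetric_differences_give_zero_z(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        z, p = wilcoxon_signed_rank(d)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0.4, 0.6, 23)
        z, p = wilcoxon_signed_rank(a + 0.3, a)
        assert p < 0.01
        assert z > 0

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0.2, 1.0, 30)
        z, p = wilcoxon_signed_rank(x)
        ref = scipy.stats.wilcoxon(
            x, zero_method="wilcox", correction=False, mode="approx"
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.array([]))


def test_odds_ratio_of_zero_is_one():
    assert odds_ratio(0.0) == 1.0
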