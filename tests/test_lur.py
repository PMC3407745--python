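"""Annual means, univariate screening, sign-constrained stepwise selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from citylur.lur import (
    backward_stepwise_fit,
    predict_no2,
    site_period_mean,
    univariate_screen,
)
from citylur.predictors import DEFAULT_SIGNS, ExpectedSignTable, Sign, assemble_predictor_table


def unconstrained(names):
    signs = {n: Sign.UNCONSTRAINED for n in DEFAULT_SIGNS.signs}
    signs.update({n: Sign.UNCONSTRAINED for n in names})
    return _table_for(signs)


def _table_for(signs):
    class _Loose(ExpectedSignTable):
        def __post_init__(self):  # free-form predictor names in tests
            pass

    return _Loose(signs)


class TestSitePeriodMean:
    def test_arithmetic_mean(self):
        rec = pd.DataFrame({"site_id": ["a"] * 3, "period": [1, 2, 3], "value": [40.0, 50.0, 60.0]})
        means, kept, dropped = site_period_mean(rec, 3)
        assert means["a"] == 50.0 and kept == ["a"] and dropped == []

    def test_incomplete_sites_dropped_and_reported(self):
        rec = pd.DataFrame(
            {
                "site_id": ["a", "a", "a", "b", "b"],
                "period": [1, 2, 3, 1, 2],
                "value": [40.0, 50.0, 60.0, 30.0, 35.0],
            }
        )
        means, kept, dropped = site_period_mean(rec, 3)
        assert kept == ["a"] and dropped == ["b"]
        assert list(means.index) == ["a"]

    def test_single_period_passthrough(self):
        rec = pd.DataFrame({"site_id": ["a", "b"], "period": [1, 1], "value": [12.0, 15.0]})
        means, kept, _ = site_period_mean(rec, 1)
        assert means["a"] == 12.0 and means["b"] == 15.0

    def test_empty_input(self):
        means, kept, dropped = site_period_mean(pd.DataFrame(columns=["site_id", "period", "value"]), 3)
        assert means.empty and kept == [] and dropped == []

    def test_seventy_site_scenario_retains_about_67(self, city, surface, sites):
        from citylur.synthetic import SamplerSpec, simulate_campaign

        seventy = pd.concat([sites, sites.iloc[:10].assign(site_id=[f"x{i}" for i in range(10)])])
        ms = simulate_campaign(city, surface, seventy, 3, SamplerSpec("s", 1, 0, 1.0), 1,
                               seed=77, missing_rate=3 / 70)
        means, kept, dropped = site_period_mean(ms.records, 3)
        assert len(kept) + len(dropped) == 70
        assert len(kept) == 70 - len(dropped)


class TestUnivariateScreen:
    def test_closed_form_slope(self):
        tab = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        res = univariate_screen(tab, np.array([0.0, 1.5, 3.0]))
        assert res.loc["x", "slope"] == pytest.approx(1.5)

    def test_constant_response_gives_zero_slopes(self, rng):
        tab = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        res = univariate_screen(tab, np.zeros(10))
        assert res["slope"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_binary_predictor_handled(self):
        tab = pd.DataFrame({"g": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]})
        res = univariate_screen(tab, np.array([1.0, 2.0, 1.1, 2.2, 0.9, 1.9]))
        assert np.isfinite(res.loc["g", "slope"])

    def test_constant_predictor_flagged(self, rng):
        tab = pd.DataFrame({"c": np.ones(8), "x": rng.normal(size=8)})
        res = univariate_screen(tab, rng.normal(size=8))
        assert bool(res.loc["c", "constant"]) and np.isnan(res.loc["c", "slope"])

    def test_matches_statsmodels(self, rng):
        tab = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=40)
        res = univariate_screen(tab, y)
        for name in tab.columns:
            f = sm.OLS(y, sm.add_constant(tab[name])).fit()
            assert res.loc[name, "slope"] == pytest.approx(f.params[name], abs=1e-10)
            assert res.loc[name, "p_value"] == pytest.approx(f.pvalues[name], abs=1e-10)


class TestBackwardStepwise:
    def test_single_informative_predictor_retained(self, rng):
        x = rng.normal(size=40)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.2, 40)
        tab = pd.DataFrame({"x": x})
        m = backward_stepwise_fit(tab, y, _table_for({"x": Sign.POSITIVE}))
        assert m.predictors == ["x"]

    def test_unconstrained_p1_keeps_full_model(self, rng):
        tab = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(size=50)
        signs = _table_for({c: Sign.UNCONSTRAINED for c in "abcd"})
        m = backward_stepwise_fit(tab, y, signs, p_remove=1.0)
        assert sorted(m.predictors) == list("abcd")
        full = sm.OLS(y, sm.add_constant(tab)).fit()
        for c in "abcd":
            assert m.coefficients[c] == pytest.approx(full.params[c], abs=1e-10)
        assert m.adjusted_r2 == pytest.approx(full.rsquared_adj, abs=1e-10)

    def test_sign_invariant_always_holds(self, rng):
        """No retained sign-constrained coefficient contradicts its expected
        direction, over many random data sets."""
        for rep in range(30):
            r = np.random.default_rng(rep)
            tab = pd.DataFrame(r.normal(size=(30, 3)), columns=["pos", "neg", "free"])
            y = r.normal(size=30)
            signs = _table_for({"pos": Sign.POSITIVE, "neg": Sign.NEGATIVE, "free": Sign.UNCONSTRAINED})
            m = backward_stepwise_fit(tab, y, signs)
            if "pos" in m.predictors:
                assert m.coefficients["pos"] >= 0
            if "neg" in m.predictors:
                assert m.coefficients["neg"] <= 0
            for name, p in m.pvalues.items():
                assert p <= 0.20 or name in ("x_coord", "y_coord")

    def test_matches_exhaustive_subset_oracle(self):
        """With one pure-noise candidate among three, the stepwise endpoint
        agrees with brute-force enumeration of all sign/p-consistent subsets
        picked by adjusted R^2."""
        r = np.random.default_rng(5)
        n = 80
        tab = pd.DataFrame(
            {"a": r.normal(size=n), "b": r.normal(size=n), "noise": r.normal(size=n)}
        )
        y = 0.6 * tab["a"].to_numpy() - 0.5 * tab["b"].to_numpy() + r.normal(0, 0.4, n)
        signs = _table_for({"a": Sign.POSITIVE, "b": Sign.NEGATIVE, "noise": Sign.UNCONSTRAINED})
        m = backward_stepwise_fit(tab, y, signs)
        assert "noise" not in m.predictors

        best, best_adj = None, -np.inf
        for k in range(1, 4):
            for sub in itertools.combinations(tab.columns, k):
                f = sm.OLS(y, sm.add_constant(tab[list(sub)])).fit()
                ok = all(f.pvalues[c] <= 0.20 for c in sub)
                ok &= all(
                    not signs.violates(c, f.params[c]) for c in sub
                )
                if ok and f.rsquared_adj > best_adj:
                    best, best_adj = sorted(sub), f.rsquared_adj
        assert sorted(m.predictors) == best
        assert m.adjusted_r2 == pytest.approx(best_adj, abs=1e-10)

    def test_coordinate_pairing_keeps_partner(self, rng):
        """A coordinate selected on merit drags its partner into the model
        regardless of the partner's p-value."""
        n = 60
        x = rng.uniform(0, 10_000, n)
        ycoord = rng.uniform(0, 10_000, n)
        z = rng.normal(size=n)
        resp = 1.0 + 3e-4 * x + rng.normal(0, 0.3, n)
        tab = pd.DataFrame({"x_coord": x, "y_coord": ycoord, "z": z})
        signs = _table_for(
            {"x_coord": Sign.UNCONSTRAINED, "y_coord": Sign.UNCONSTRAINED, "z": Sign.UNCONSTRAINED}
        )
        m = backward_stepwise_fit(tab, resp, signs)
        assert "x_coord" in m.predictors and "y_coord" in m.predictors
        assert m.pvalues["x_coord"] <= 0.20  # merit; the partner may be anything

    def test_noiseless_recovery_is_exact(self, city, sites):
        from citylur.synthetic import SurfaceParams, simulate_true_surface

        betas = {"dist_centre": -3e-5, "altitude": -2e-3, "traffic_density_150": 1e-3}
        surf = simulate_true_surface(city, SurfaceParams(beta0=4.0, betas=betas, noise_sd=0.0), seed=1)
        tab = assemble_predictor_table(sites[["x", "y"]].to_numpy(), city)
        y = surf.log_concentration(sites[["x", "y"]].to_numpy(), predictor_table=tab)
        m = backward_stepwise_fit(tab, y, DEFAULT_SIGNS)
        for name, b in betas.items():
            assert m.coefficients[name] == pytest.approx(b, abs=1e-6)
        assert m.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        for name, b in m.coefficients.items():
            if name not in betas:
                assert abs(b * tab[name].std()) < 1e-6  # numerically null effect

    def test_intercept_only_fallback_warns(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=20)})
        y = rng.normal(size=20) * 0 + 3.0 + rng.normal(0, 1, 20)
        signs = _table_for({"x": Sign.UNCONSTRAINED})
        with pytest.warns(UserWarning, match="intercept-only"):
            m = backward_stepwise_fit(tab, y, signs, p_remove=1e-9)
        assert m.predictors == [] and m.intercept == pytest.approx(np.mean(y))


class TestPredict:
    def test_intercept_only(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=20)})
        y = np.full(20, np.log(45.0)) + rng.normal(0, 1e-3, 20)
        with pytest.warns(UserWarning):
            m = backward_stepwise_fit(tab, y, _table_for({"x": Sign.UNCONSTRAINED}), p_remove=1e-12)
        pred = predict_no2(m, pd.DataFrame({"x": [0.0]}))
        assert pred[0] == pytest.approx(45.0, rel=1e-3)

    def test_hand_arithmetic(self, rng):
        # exp(3.5 - 2e-5 * 10000) = exp(3.3)
        tab = pd.DataFrame({"dist_centre": rng.uniform(0, 20_000, 30)})
        y = 3.5 - 2e-5 * tab["dist_centre"].to_numpy()
        m = backward_stepwise_fit(tab, y, _table_for({"dist_centre": Sign.NEGATIVE}))
        pred = predict_no2(m, pd.DataFrame({"dist_centre": [10_000.0]}))
        assert pred[0] == pytest.approx(np.exp(3.3), rel=1e-9)
        assert np.exp(3.3) == pytest.approx(27.11, abs=0.01)

    def test_monotone_in_negative_predictor(self, rng):
        tab = pd.DataFrame({"dist_centre": rng.uniform(0, 20_000, 30)})
        y = 3.5 - 2e-5 * tab["dist_centre"].to_numpy() + rng.normal(0, 0.01, 30)
        m = backward_stepwise_fit(tab, y, _table_for({"dist_centre": Sign.NEGATIVE}))
        lo, hi = predict_no2(m, pd.DataFrame({"dist_centre": [1_000.0, 9_000.0]}))
        assert hi < lo

    def test_missing_column_is_named(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=30)})
        y = 2.0 + 0.5 * tab["x"].to_numpy() + rng.normal(0, 0.1, 30)
        m = backward_stepwise_fit(tab, y, _table_for({"x": Sign.UNCONSTRAINED}))
        with pytest.raises(KeyError, match="x"):
            predict_no2(m, pd.DataFrame({"other": [1.0]}))

    def test_predictions_positive(self, rng):
        tab = pd.DataFrame({"x": rng.normal(size=30)})
        y = rng.normal(size=30)
        m = backward_stepwise_fit(tab, y, _table_for({"x": Sign.UNCONSTRAINED}), p_remove=1.0)
        assert (predict_no2(m, tab) > 0).all()
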