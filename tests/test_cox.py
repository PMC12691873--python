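import numpy as np
import pandas as pd
import pytest

from mesfsurv import (
    CovariateSpec,
    Dataset,
    breslow_baseline,
    encode_design,
    fit_cox,
    hazard_ratios,
    schoenfeld_ph_test,
    vif,
)
from mesfsurv.cox import MonotoneLikelihoodWarning
from mesfsurv.synthetic import covariate_specs


def _ds(time, event, x):
    return Dataset(
        pd.DataFrame(
            {
                "region_id": ["a"] * len(time),
                "time_months": time,
                "event": event,
                "x": x,
            }
        )
    )


@pytest.fixture(scope="module")
def three_record_fit():
    ds = _ds([1.0, 2.0, 3.0], [1, 1, 0], [1.0, 0.0, 1.0])
    return fit_cox(ds, [CovariateSpec("x", "continuous")])


def cox_loglik_oracle(t, ev, x, beta):
    """Direct risk-set log partial likelihood (tie-free data, 1 covariate)."""
    ll = 0.0
    for i in np.flatnonzero(ev):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestFitCox:
    def test_closed_form_three_records(self, three_record_fit):
        assert np.isclose(three_record_fit.params.iloc[0], -np.log(2) / 2, atol=1e-8)
        assert np.isclose(three_record_fit.loglik_null, -np.log(6), atol=1e-12)
        assert three_record_fit.converged

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        grid = np.arange(-2.0, 2.0001, 1e-4)
        for _ in range(20):
            n = 10
            t = rng.exponential(1.0, n)
            ev = rng.binomial(1, 0.7, n)
            ev[rng.integers(n)] = 1
            x = rng.standard_normal(n)
            lls = np.array([cox_loglik_oracle(t, ev, x, b) for b in grid])
            beta_grid = grid[np.argmax(lls)]
            fit = fit_cox(_ds(t, ev, x), [CovariateSpec("x", "continuous")],
                          ties="breslow")
            if abs(fit.params.iloc[0]) < 1.99:  # optimum inside the grid
                assert abs(fit.params.iloc[0] - beta_grid) < 2e-4

    def test_lifelines_cross_check(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.binomial(1, 0.4, n).astype(float)
        x2 = rng.standard_normal(n)
        t = rng.exponential(1 / (0.05 * np.exp(0.7 * x1 - 0.3 * x2)))
        t = np.ceil(t)  # monthly grid -> heavy ties, exercises Efron
        c = 30.0
        ev = (t <= c).astype(int)
        tt = np.minimum(t, c)
        df = pd.DataFrame({"T": tt, "E": ev, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        ds = Dataset(
            pd.DataFrame(
                {"region_id": "a", "time_months": tt, "event": ev,
                 "x1": x1, "x2": x2}
            )
        )
        fit = fit_cox(
            ds,
            [CovariateSpec("x1", "continuous"), CovariateSpec("x2", "continuous")],
            ties="efron",
        )
        assert np.allclose(fit.params.to_numpy(),
                           cph.params_[["x1", "x2"]].to_numpy(), atol=1e-4)
        assert np.isclose(fit.loglik, cph.log_likelihood_, atol=1e-4)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(8)
        n = 150
        t = rng.exponential(5, n)
        ev = rng.binomial(1, 0.6, n)
        ev[0] = 1
        x = rng.standard_normal(n)
        ds = _ds(t, ev, x)
        spec = [CovariateSpec("x", "continuous")]
        fe = fit_cox(ds, spec, ties="efron")
        fb = fit_cox(ds, spec, ties="breslow")
        assert np.allclose(fe.params, fb.params, atol=1e-10)
        assert np.isclose(fe.loglik, fb.loglik, atol=1e-10)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        n = 100
        t = rng.exponential(5, n)
        ev = rng.binomial(1, 0.5, n)
        ev[0] = 1
        x = rng.standard_normal(n)
        spec = [CovariateSpec("x", "continuous")]
        f1 = fit_cox(_ds(t, ev, x), spec)
        f2 = fit_cox(_ds(t, ev, x + 100.0), spec)
        assert np.allclose(f1.params, f2.params, atol=1e-6)

    def test_score_small_at_optimum(self, three_record_fit):
        eng = three_record_fit._engine
        _, score, _ = eng.loglik_score_info(three_record_fit.params.to_numpy())
        assert np.max(np.abs(score)) < 1e-6

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox(_ds([1.0, 2.0], [0, 0], [0.0, 1.0]),
                    [CovariateSpec("x", "continuous")])

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.standard_normal(n)
        ds = Dataset(
            pd.DataFrame(
                {"region_id": "a", "time_months": rng.exponential(1, n) + 0.1,
                 "event": rng.binomial(1, 0.8, n), "x": x, "y": 2 * x}
            )
        )
        with pytest.raises(ValueError, match="rank deficient"):
            fit_cox(ds, [CovariateSpec("x", "continuous"),
                         CovariateSpec("y", "continuous")])

    def test_monotone_likelihood_flagged(self):
        # covariate perfectly orders the event times -> divergent coefficient
        t = np.arange(1.0, 9.0)
        ev = np.ones(8, dtype=int)
        x = -t
        with pytest.warns(MonotoneLikelihoodWarning):
            fit_cox(_ds(t, ev, x), [CovariateSpec("x", "continuous")])


class TestEncodeDesign:
    def test_reference_level_all_zero(self):
        ds = Dataset(
            pd.DataFrame(
                {"region_id": ["a"], "time_months": [1.0], "event": [1],
                 "age_group": ["18-44"]}
            )
        )
        spec = CovariateSpec(
            "age_group", "categorical", levels=("18-44", "45-64", "65-74", "75+")
        )
        X, names = encode_design(ds, [spec])
        assert names == ["age_group[45-64]", "age_group[65-74]", "age_group[75+]"]
        assert np.all(X == 0)

    def test_registry_spec_has_24_columns(self):
        specs = covariate_specs("registry")
        n_cols = 0
        for s in specs:
            n_cols += len(s.levels) - 1 if s.kind == "categorical" else 1
        assert n_cols == 24

    def test_unseen_level_rejected(self):
        ds = Dataset(
            pd.DataFrame(
                {"region_id": ["a"], "time_months": [1.0], "event": [1],
                 "age_group": ["age 200+"]}
            )
        )
        spec = CovariateSpec("age_group", "categorical", levels=("18-44", "45-64"))
        with pytest.raises(ValueError, match="unseen level"):
            encode_design(ds, [spec])

    def test_missing_values_rejected(self):
        ds = Dataset(
            pd.DataFrame(
                {"region_id": ["a", "a"], "time_months": [1.0, 2.0],
                 "event": [1, 0], "x": [1.0, np.nan]}
            )
        )
        with pytest.raises(ValueError, match="missing"):
            encode_design(ds, [CovariateSpec("x", "continuous")])


class TestHazardRatios:
    def test_null_coefficient(self):
        fit_like = type("F", (), {})()
        fit_like.params = pd.Series({"x": 0.0})
        fit_like.se = pd.Series({"x": 0.5})
        tab = hazard_ratios(fit_like)
        assert np.isclose(tab.loc["x", "HR"], 1.0)
        # CI symmetric about 1 on the log scale
        assert np.isclose(tab.loc["x", "CI_low"] * tab.loc["x", "CI_high"], 1.0)

    def test_closed_form_hr(self, three_record_fit):
        tab = hazard_ratios(three_record_fit)
        assert np.isclose(tab["HR"].iloc[0], 2 ** -0.5, atol=1e-6)
        assert tab["CI_low"].iloc[0] < tab["HR"].iloc[0] < tab["CI_high"].iloc[0]


class TestSchoenfeld:
    @staticmethod
    def _sim_ph(rng, n=200):
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        c = np.quantile(t, 0.7)
        return np.minimum(t, c), (t <= c).astype(int), x

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            t, ev, x = self._sim_ph(rng)
            fit = fit_cox(_ds(t, ev, x), [CovariateSpec("x", "continuous")])
            res = schoenfeld_ph_test(fit)
            rejections += res["table"]["p"].iloc[0] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 0.04

    def test_power_against_sign_reversal(self):
        # effect +1 before t0, -1 after: a textbook PH violation
        rng = np.random.default_rng(77)
        lam, beta, t0 = 0.1, 1.0, 7.0
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 500
            x = rng.standard_normal(n)
            e = rng.exponential(size=n)
            h1 = lam * np.exp(beta * x)
            h2 = lam * np.exp(-beta * x)
            t = np.where(e < h1 * t0, e / h1, t0 + (e - h1 * t0) / h2)
            c = 60.0
            ev = (t <= c).astype(int)
            tt = np.minimum(t, c)
            fit = fit_cox(_ds(tt, ev, x), [CovariateSpec("x", "continuous")])
            res = schoenfeld_ph_test(fit)
            rejections += res["table"]["p"].iloc[0] < 0.05
        assert rejections / n_rep > 0.8

    def test_single_event_rejected(self):
        fit = fit_cox(_ds([1.0, 2.0, 3.0], [1, 0, 0], [1.0, 0.0, 1.0]),
                      [CovariateSpec("x", "continuous")])
        with pytest.raises(ValueError):
            schoenfeld_ph_test(fit)


class TestVif:
    def test_orthogonal_columns(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        out = vif(X, ["a", "b"])
        assert np.allclose(out, 1.0)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(np.column_stack([x, x, rng.standard_normal(50)]))
        assert np.isinf(out.iloc[0]) and np.isinf(out.iloc[1])

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(2)
        n = 20000
        z = rng.standard_normal(n)
        x1 = z
        x2 = 0.6 * z + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        out = vif(np.column_stack([x1, x2]))
        assert np.allclose(out, 1.0 / (1.0 - 0.36), atol=0.05)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif(np.column_stack([np.ones(10), np.arange(10.0)]))


class TestBreslowBaseline:
    def test_nelson_aalen_reduction(self):
        # beta = 0, single event among m at risk -> first increment 1/m
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ev = np.array([1, 0, 0, 0, 0])
        # constant covariate is unidentifiable; use a tiny-variance one at beta~0
        ds = _ds(t, ev, [0.0, 1e-8, 0.0, 1e-8, 0.0])
        fit = fit_cox(ds, [CovariateSpec("x", "continuous")])
        bl = breslow_baseline(fit)
        assert np.isclose(bl["cumulative_hazard"].iloc[0], 1.0 / 5.0, atol=1e-6)

    def test_flat_after_last_event(self):
        t = np.array([1.0, 2.0, 3.0, 9.0, 10.0])
        ev = np.array([1, 1, 0, 0, 0])
        ds = _ds(t, ev, [1.0, 0.0, 1.0, 0.0, 1.0])
        fit = fit_cox(ds, [CovariateSpec("x", "continuous")])
        bl = breslow_baseline(fit)
        assert bl["time"].max() == 2.0  # no steps beyond the last event

    def test_exponential_large_sample(self):
        rng = np.random.default_rng(10)
        n, lam = 2000, 0.05
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (lam * np.exp(0.3 * x)))
        c = 40.0
        ev = (t <= c).astype(int)
        tt = np.minimum(t, c)
        fit = fit_cox(_ds(tt, ev, x), [CovariateSpec("x", "continuous")])
        bl = breslow_baseline(fit)
        inside = bl["time"] <= 30
        err = np.abs(bl.loc[inside, "cumulative_hazard"] - lam * bl.loc[inside, "time"])
        assert err.max() < 0.1
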