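"""Segmented ITS: aggregation, exclusion, design coding, estimation."""

import numpy as np
import pandas as pd
import pytest

from hemsits.its import (InterruptedTimeSeriesRegressor, aggregate_monthly,
                         build_design, fit_its, flag_excluded_months,
                         select_error_model)
from hemsits.simulate import simulate_ma1_shocks

BETA = np.array([31.05, 0.05, -2.0, -0.13, 1.1])
TPI = 24


def _design36():
    t = np.arange(36)
    cal = (t % 12) + 1  # study starts in January
    return t, cal, build_design(t, cal, TPI)


def _series(means, start="2017-01"):
    months = pd.period_range(start, periods=len(means), freq="M")
    return pd.DataFrame({
        "t": np.arange(len(means)),
        "calendar_month": months,
        "mean_response": means,
        "n_missions": 10,
        "included": pd.notna(means),
        "exclusion_reason": "none",
    })


class TestAggregateMonthly:
    def _missions(self, times_by_month):
        rows = []
        for month, times in times_by_month.items():
            for i, rt in enumerate(times):
                alarm = pd.Timestamp(f"{month}-03 10:00", tz="UTC")
                rows.append({
                    "mission_id": f"{month}-{i}",
                    "alarm_time": alarm,
                    "on_scene_time": alarm + pd.Timedelta(minutes=rt),
                })
        return pd.DataFrame(rows)

    def test_arithmetic_mean_per_month(self):
        df = self._missions({"2017-01": [30, 31, 32]})
        out = aggregate_monthly(df)
        assert out.loc[0, "mean_response"] == pytest.approx(31.0)
        assert out.loc[0, "n_missions"] == 3

    def test_single_mission_month(self):
        out = aggregate_monthly(self._missions({"2017-01": [28.5]}))
        assert out.loc[0, "mean_response"] == pytest.approx(28.5)

    def test_weighted_mean_of_monthly_means_is_grand_mean(self, rng):
        times = {f"2017-{m:02d}": list(rng.uniform(20, 45, rng.integers(1, 9)))
                 for m in range(1, 13)}
        df = self._missions(times)
        out = aggregate_monthly(df)
        grand = np.concatenate(list(times.values())).mean()
        weighted = (out["mean_response"] * out["n_missions"]).sum() / out["n_missions"].sum()
        assert weighted == pytest.approx(grand, rel=1e-12)

    def test_empty_month_keeps_flagged_row(self):
        out = aggregate_monthly(self._missions(
            {"2017-01": [30], "2017-03": [32]}))
        assert len(out) == 3
        assert not out.loc[1, "included"]
        assert out.loc[1, "exclusion_reason"] == "empty month"


class TestFlagExcludedMonths:
    def test_planted_34_sd_outlier_flagged_at_threshold_3(self, rng):
        means = 31.0 + rng.normal(0, 1.0, 36)
        resid_sd = np.std(np.delete(means, [24]), ddof=1)
        means[35] = np.delete(means, [24, 35]).mean() + 3.4 * resid_sd
        out = flag_excluded_months(_series(means), "2019-01", z_threshold=3.0)
        assert out.loc[35, "exclusion_reason"] == "outlier"
        assert not out.loc[35, "included"]

    def test_flat_series_flags_only_intervention_month(self):
        out = flag_excluded_months(_series(np.full(36, 31.0)), "2019-01")
        assert not out.loc[24, "included"]
        assert out.loc[24, "exclusion_reason"] == "intervention month"
        assert out["included"].sum() == 35

    def test_study_configuration_yields_24_pre_and_10_post_points(self, rng):
        # 24 pre months, 12 post; the intervention month and one extreme
        # December-2019 outlier are dropped, leaving 24 + 10 included
        means = 31.0 + rng.normal(0, 1.0, 36)
        means[35] += 6.0  # far outlier
        out = flag_excluded_months(_series(means), "2019-01")
        pre = out[(out["t"] < TPI) & out["included"]]
        post = out[(out["t"] > TPI) & out["included"]]
        assert len(pre) == 24
        assert len(post) == 10

    def test_intervention_month_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            flag_excluded_months(_series(np.full(36, 31.0)), "2030-01")


class TestBuildDesign:
    def test_origin_january_row(self):
        _, _, X = _design36()
        np.testing.assert_array_equal(X[0], [1, 0, 0, 0, 1])

    def test_first_post_month_carries_step_one_ramp_zero_then_one(self):
        _, _, X = _design36()
        # intervention month itself: step 1, ramp 0
        np.testing.assert_array_equal(X[24], [1, 24, 1, 0, 1])
        # first included post month (t = 25, February => winter)
        np.testing.assert_array_equal(X[25], [1, 25, 1, 1, 1])

    def test_pre_months_have_zero_step_and_ramp(self):
        _, _, X = _design36()
        assert (X[:24, 2] == 0).all()
        assert (X[:24, 3] == 0).all()

    def test_winter_indicator_october_through_march(self):
        t = np.arange(12)
        X = build_design(t, t + 1, 6)
        np.testing.assert_array_equal(
            X[:, 4], [1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1])

    def test_tpi_outside_window_rejected(self):
        with pytest.raises(ValueError, match="tpi"):
            build_design(np.arange(10), np.arange(10) % 12 + 1, 50)


class TestFit:
    def test_noiseless_series_recovers_coefficients_exactly(self):
        t, cal, X = _design36()
        y = X @ BETA
        mask = t != TPI
        m = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="white").fit(
            np.column_stack([t, cal])[mask], y[mask])
        np.testing.assert_allclose(m.beta_, BETA, atol=1e-6)
        assert m.r2_ == pytest.approx(1.0)

    def test_white_noise_spec_equals_ols(self, rng):
        import statsmodels.api as sm
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 1.5, 36)
        mask = t != TPI
        m = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="white").fit(
            np.column_stack([t, cal])[mask], y[mask])
        ols = sm.OLS(y[mask], X[mask]).fit()
        np.testing.assert_allclose(m.beta_, ols.params, atol=1e-8)

    def test_level_shift_invariance(self, rng):
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 1.0, 36)
        mask = t != TPI
        Xy = np.column_stack([t, cal])[mask]
        m1 = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="ma1").fit(Xy, y[mask])
        m2 = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="ma1").fit(Xy, y[mask] + 10.0)
        assert m2.beta_[0] == pytest.approx(m1.beta_[0] + 10.0, abs=1e-3)
        np.testing.assert_allclose(m2.beta_[1:], m1.beta_[1:], atol=1e-3)

    def test_time_origin_shift_preserves_effects_and_pvalues(self, rng):
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 1.0, 36)
        mask = t != TPI
        m1 = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="white").fit(
            np.column_stack([t, cal])[mask], y[mask])
        # shift the origin by 6 months (calendar follows: t=0 becomes July)
        m2 = InterruptedTimeSeriesRegressor(tpi=TPI + 6, error_spec="white").fit(
            np.column_stack([t + 6, cal])[mask], y[mask])
        np.testing.assert_allclose(m2.beta_[2:], m1.beta_[2:], atol=1e-8)
        np.testing.assert_allclose(m2.pvalues_[2:4], m1.pvalues_[2:4], atol=1e-8)

    def test_r2_non_decreasing_with_step_and_ramp(self, rng):
        import statsmodels.api as sm
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 1.0, 36)
        mask = t != TPI
        full = sm.OLS(y[mask], X[mask]).fit()
        reduced = sm.OLS(y[mask], X[mask][:, [0, 1, 4]]).fit()
        assert full.rsquared >= reduced.rsquared - 1e-12

    def test_too_few_months_rejected(self):
        t = np.arange(8)
        with pytest.raises(ValueError, match=">= 10"):
            InterruptedTimeSeriesRegressor(tpi=4, error_spec="white").fit(
                np.column_stack([t, t % 12 + 1]), np.full(8, 31.0))

    def test_rank_deficiency_rejected(self):
        # all months post-intervention: step column is constant => collinear
        t = np.arange(30, 42)
        with pytest.raises(ValueError, match="rank"):
            InterruptedTimeSeriesRegressor(tpi=30, error_spec="white").fit(
                np.column_stack([t, t % 12 + 1]), np.linspace(30, 32, 12))


class TestCounterfactual:
    def _fitted(self, rng):
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 0.8, 36)
        mask = t != TPI
        m = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="white").fit(
            np.column_stack([t, cal])[mask], y[mask])
        return m, t, cal

    def test_pre_period_counterfactual_equals_fitted_mean(self, rng):
        m, t, cal = self._fitted(rng)
        X = np.column_stack([t, cal])[:TPI]
        np.testing.assert_allclose(m.counterfactual(X), m.predict(X), atol=1e-12)

    def test_null_intervention_collapses_to_fitted_mean(self):
        t, cal, X = _design36()
        beta_null = np.array([31.05, 0.05, 0.0, 0.0, 1.1])
        y = X @ beta_null
        mask = t != TPI
        m = InterruptedTimeSeriesRegressor(tpi=TPI, error_spec="white").fit(
            np.column_stack([t, cal])[mask], y[mask])
        Xall = np.column_stack([t, cal])
        np.testing.assert_allclose(m.counterfactual(Xall), m.predict(Xall),
                                   atol=1e-6)

    def test_fitted_minus_counterfactual_is_beta2_plus_beta3_ramp(self, rng):
        m, t, cal = self._fitted(rng)
        Xpost = np.column_stack([t, cal])[TPI + 1:]
        gap = m.predict(Xpost) - m.counterfactual(Xpost)
        expected = m.beta_[2] + m.beta_[3] * (Xpost[:, 0] - TPI)
        np.testing.assert_allclose(gap, expected, atol=1e-10)


class TestModelSelection:
    def test_duplicate_candidates_resolved_by_listed_order(self, rng):
        t, cal, X = _design36()
        y = X @ BETA + rng.normal(0, 1.0, 36)
        series = _series(np.where(t == TPI, np.nan, y))
        m = select_error_model(series, TPI, candidates=("white", "white"))
        assert m.error_spec == "white"

    def test_strong_ma1_selected_in_majority_of_replicates(self):
        t, cal, X = _design36()
        wins = 0
        n_rep = 40
        for s in range(n_rep):
            rng = np.random.default_rng(40_000 + s)
            y = X @ BETA + simulate_ma1_shocks(36, 0.6, 1.0, rng)
            series = _series(np.where(t == TPI, np.nan, y))
            m = select_error_model(series, TPI, candidates=("white", "ma1"))
            wins += m.error_spec == "ma1"
        assert wins > n_rep / 2

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_error_model(_series(np.full(36, 31.0)), TPI, candidates=())

    def test_all_failures_reported_with_diagnostics(self):
        series = _series(np.full(36, np.nan))
        with pytest.raises((RuntimeError, ValueError)):
            select_error_model(series, TPI, candidates=("white", "ma1"))


def test_fit_its_wrapper_uses_included_months_only(rng):
    t, cal, X = _design36()
    y = X @ BETA + rng.normal(0, 1.0, 36)
    series = _series(y)
    series.loc[24, "included"] = False
    series.loc[24, "mean_response"] = 99.0  # must be ignored
    m = fit_its(series, TPI, error_spec="white")
    assert m.nobs_ == 35
    assert abs(m.beta_[0] - 31.05) < 2.0
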