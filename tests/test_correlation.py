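import numpy as np
import pandas as pd
import pytest

from budchill.correlate import (
    CorrelationError,
    build_covariates,
    correlate,
    correlation_matrix,
    expression_onset_temperature,
    fit_line_by_group,
)
from budchill.simulate import SimulationConfig, simulate_temperature
from helpers import constant_series, make_series, profile_matrix


def temp_profiles(temps_by_date, expr_fn, gene="G", cultivars=("A", "B")):
    """Profiles whose expression is a function of the date's temperature."""
    dates = pd.DatetimeIndex(sorted(temps_by_date))
    values = np.array(
        [[expr_fn(temps_by_date[d], c) for d in dates for c in cultivars]]
    )
    return profile_matrix(values, genes=[gene], dates=dates, cultivars=cultivars)


class TestBuildCovariates:
    def test_constant_chill_series_full_windows(self):
        series = constant_series(5.0, 24 * 40)
        dates = ["2018-01-20", "2018-01-27"]
        cov = build_covariates(series, dates, window_days=14)
        assert (cov["ch_sum_14d"] == 336.0).all()
        assert (~cov["truncated"]).all()
        assert np.allclose(cov["mean_daily_temp"], 5.0)

    def test_warm_series_zero_chill(self):
        series = constant_series(20.0, 24 * 40)
        cov = build_covariates(series, ["2018-01-20"], window_days=14)
        assert cov["ch_sum_14d"].iloc[0] == 0.0
        assert cov["cp_sum_14d"].iloc[0] == 0.0

    def test_early_date_flagged_truncated(self):
        series = constant_series(5.0, 24 * 40)
        cov = build_covariates(series, ["2018-01-08", "2018-01-20"], window_days=14)
        assert bool(cov["truncated"].iloc[0]) is True
        assert bool(cov["truncated"].iloc[1]) is False
        assert cov["ch_sum_14d"].iloc[0] < 336.0

    def test_date_outside_series_rejected(self):
        series = constant_series(5.0, 24 * 10)
        with pytest.raises(CorrelationError, match="outside"):
            build_covariates(series, ["2019-06-01"])


class TestCorrelate:
    def _setup(self, expr_fn, n_dates=10, seed=0):
        rng = np.random.default_rng(seed)
        hours = 24 * (7 * n_dates + 20)
        temps = rng.uniform(0, 15, hours)
        series = make_series(temps, start="2017-11-01")
        dates = pd.date_range("2017-11-20", periods=n_dates, freq="7D")
        cov = build_covariates(series, dates, window_days=14)
        temps_by_date = dict(zip(dates, cov["mean_daily_temp"]))
        prof = temp_profiles(temps_by_date, expr_fn)
        return prof, cov

    def test_perfect_linear_gene_has_r_minus_one(self):
        prof, cov = self._setup(lambda t, c: 10.0 - 0.5 * t)
        rep = correlate(prof, cov, grouping="pooled",
                        covariate_cols=["mean_daily_temp"])
        assert rep["r"].iloc[0] == pytest.approx(-1.0, abs=1e-9)
        assert rep["p"].iloc[0] < 1e-6
        assert rep["slope"].iloc[0] == pytest.approx(-0.5, abs=1e-9)

    def test_constant_expression_reported_missing_with_reason(self):
        prof, cov = self._setup(lambda t, c: 3.0)
        rep = correlate(prof, cov, grouping="pooled",
                        covariate_cols=["mean_daily_temp"])
        assert np.isnan(rep["r"].iloc[0])
        assert "zero variance" in rep["reason"].iloc[0]

    def test_r_invariant_to_affine_rescaling(self):
        prof, cov = self._setup(lambda t, c: 8.0 - 0.4 * t + 0.1 * np.sin(t))
        rep1 = correlate(prof, cov, grouping="pooled",
                         covariate_cols=["mean_daily_temp"])
        scaled = profile_matrix(prof.values.to_numpy() * 7.5 + 2.0,
                                genes=list(prof.values.index),
                                dates=prof.values.columns.get_level_values("date").unique())
        rep2 = correlate(scaled, cov, grouping="pooled",
                         covariate_cols=["mean_daily_temp"])
        assert rep2["r"].iloc[0] == pytest.approx(rep1["r"].iloc[0], abs=1e-9)

    def test_permutation_null_calibration(self):
        """|r| of an unrelated covariate exceeds the permutation 95th
        percentile in roughly 5% of replicates."""
        rng = np.random.default_rng(12)
        n, reps = 28, 1000
        x = rng.normal(0, 1, n)
        exceed = 0
        y0 = rng.normal(0, 1, n)
        perm_rs = np.array([abs(np.corrcoef(np.random.default_rng(i).permutation(x), y0)[0, 1])
                            for i in range(1000)])
        q95 = np.quantile(perm_rs, 0.95)
        for _ in range(reps):
            y = rng.normal(0, 1, n)
            if abs(np.corrcoef(x, y)[0, 1]) > q95:
                exceed += 1
        assert 0.02 < exceed / reps < 0.09

    def test_groupings_report_pooled_and_per_cultivar(self):
        prof, cov = self._setup(lambda t, c: 5.0 - 0.3 * t + (1.0 if c == "A" else 0.0))
        rep = correlate(prof, cov, grouping="both",
                        covariate_cols=["mean_daily_temp"])
        assert set(rep["group"]) == {"pooled", "A", "B"}
        pooled_n = rep.loc[rep.group == "pooled", "n"].iloc[0]
        per_n = rep.loc[rep.group == "A", "n"].iloc[0]
        assert pooled_n == 2 * per_n


class TestFitLineByGroup:
    def test_planted_group_slopes_recovered(self):
        rng = np.random.default_rng(3)
        dates = pd.date_range("2017-11-01", periods=20, freq="7D")
        temps = {d: rng.uniform(0, 14) for d in dates}

        def expr(t, c):
            slope = -0.8 if c == "A" else -0.3
            return 14.0 + slope * t + rng.normal(0, 0.1)

        prof = temp_profiles(temps, expr)
        cov = pd.DataFrame(
            {"mean_daily_temp": [temps[d] for d in dates], "truncated": False},
            index=pd.Index(dates, name="date"),
        )
        out = fit_line_by_group(prof, cov, "G", "mean_daily_temp")
        slopes = dict(zip(out["group"], out["slope"]))
        assert slopes["A"] == pytest.approx(-0.8, rel=0.1)
        assert slopes["B"] == pytest.approx(-0.3, rel=0.1)
        assert out.loc[0, "slope_difference"] == pytest.approx(
            slopes["A"] - slopes["B"], abs=1e-12
        )

    def test_identical_groups_have_zero_slope_difference(self):
        dates = pd.date_range("2017-11-01", periods=8, freq="7D")
        temps = {d: float(i) for i, d in enumerate(dates)}
        prof = temp_profiles(temps, lambda t, c: 2.0 + 0.5 * t)
        cov = pd.DataFrame(
            {"mean_daily_temp": [temps[d] for d in dates], "truncated": False},
            index=pd.Index(dates, name="date"),
        )
        out = fit_line_by_group(prof, cov, "G", "mean_daily_temp")
        assert out.loc[0, "slope_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_single_group_has_no_difference_column(self):
        dates = pd.date_range("2017-11-01", periods=8, freq="7D")
        temps = {d: float(i) for i, d in enumerate(dates)}
        prof = temp_profiles(temps, lambda t, c: 2.0 + 0.5 * t)
        cov = pd.DataFrame(
            {"mean_daily_temp": [temps[d] for d in dates], "truncated": False},
            index=pd.Index(dates, name="date"),
        )
        out = fit_line_by_group(prof, cov, "G", "mean_daily_temp", groups=["A"])
        assert "slope_difference" not in out.columns

    def test_absent_group_rejected(self):
        dates = pd.date_range("2017-11-01", periods=8, freq="7D")
        temps = {d: float(i) for i, d in enumerate(dates)}
        prof = temp_profiles(temps, lambda t, c: 2.0 + 0.5 * t)
        cov = pd.DataFrame(
            {"mean_daily_temp": [temps[d] for d in dates], "truncated": False},
            index=pd.Index(dates, name="date"),
        )
        with pytest.raises(CorrelationError, match="absent"):
            fit_line_by_group(prof, cov, "G", "mean_daily_temp", groups=["Z"])


class TestCorrelationMatrix:
    def _reports(self):
        return pd.DataFrame(
            [
                dict(gene="G1", covariate="mean_daily_temp", group="pooled",
                     n=10, r=-0.8, p=0.001, slope=-0.5, intercept=3.0),
                dict(gene="G1", covariate="ch_sum_14d", group="pooled",
                     n=10, r=0.6, p=0.01, slope=0.1, intercept=1.0),
                dict(gene="G2", covariate="mean_daily_temp", group="pooled",
                     n=10, r=np.nan, p=np.nan, slope=np.nan, intercept=np.nan),
                dict(gene="G2", covariate="ch_sum_14d", group="pooled",
                     n=10, r=0.2, p=0.5, slope=0.05, intercept=2.0),
            ]
        )

    def test_shape_and_consistency(self):
        mats = correlation_matrix(self._reports())
        r = mats["pooled"]["r"]
        assert r.shape == (2, 2)
        assert r.loc["G1", "mean_daily_temp"] == -0.8
        assert mats["pooled"]["p"].loc["G1", "ch_sum_14d"] == 0.01

    def test_missing_r_propagated_as_nan(self):
        mats = correlation_matrix(self._reports())
        assert np.isnan(mats["pooled"]["r"].loc["G2", "mean_daily_temp"])

    def test_empty_reports_rejected(self):
        with pytest.raises(CorrelationError):
            correlation_matrix(pd.DataFrame())


class TestOnsetTemperature:
    def _cov(self, temps):
        dates = pd.date_range("2017-11-01", periods=len(temps), freq="7D")
        return dates, pd.DataFrame(
            {"mean_daily_temp": temps, "truncated": False},
            index=pd.Index(dates, name="date"),
        )

    def test_max_temperature_of_expressed_timepoints(self):
        dates, cov = self._cov([2.0, 5.0, 9.0, 12.0, 15.0])
        values = np.repeat([1.0, 1.0, 1.0, 0.0, 0.0], 2)[None, :]
        prof = profile_matrix(values, genes=["G"], dates=dates)
        out = expression_onset_temperature(prof, cov, "G", detection_floor=0.5)
        assert out["onset_temp"] == 9.0

    def test_always_expressed_flagged_no_contrast(self):
        dates, cov = self._cov([2.0, 5.0, 9.0])
        prof = profile_matrix(np.ones((1, 6)), genes=["G"], dates=dates)
        out = expression_onset_temperature(prof, cov, "G", detection_floor=0.5)
        assert out["onset_temp"] == 9.0
        assert "no contrast" in out["reason"]

    def test_never_expressed_missing_with_reason(self):
        dates, cov = self._cov([2.0, 5.0, 9.0])
        prof = profile_matrix(np.zeros((1, 6)), genes=["G"], dates=dates)
        out = expression_onset_temperature(prof, cov, "G", detection_floor=0.5)
        assert np.isnan(out["onset_temp"])
        assert "never expressed" in out["reason"]

    def test_step_function_gene_recovers_planted_threshold(self):
        cfg = SimulationConfig(seed=9)
        series = simulate_temperature(cfg)
        dates = cfg.sampling_dates
        cov = build_covariates(series, dates, window_days=14)
        t_star = 9.2
        expressed = (cov["mean_daily_temp"] < t_star).to_numpy()
        values = np.repeat(np.where(expressed, 2.0, 0.0), 2)[None, :]
        prof = profile_matrix(values, genes=["G"], dates=dates,
                              cultivars=cfg.cultivars)
        out = expression_onset_temperature(prof, cov, "G", detection_floor=0.5)
        assert out["onset_temp"] <= t_star
        temps = np.sort(cov["mean_daily_temp"].to_numpy())
        spacing = np.max(np.diff(temps))
        assert t_star - out["onset_temp"] <= spacing + 1e-9


class TestPoolingAttenuation:
    def test_distinct_intercepts_attenuate_pooled_r(self):
        rng = np.random.default_rng(21)
        dates = pd.date_range("2017-11-01", periods=28, freq="7D")
        temps = {d: rng.uniform(0, 14) for d in dates}

        def expr(t, c):
            if c == "A":
                return 20.0 - 0.9 * t + rng.normal(0, 1.2)
            return 14.0 - 0.6 * t + rng.normal(0, 1.2)

        prof = temp_profiles(temps, expr)
        cov = pd.DataFrame(
            {"mean_daily_temp": [temps[d] for d in dates], "truncated": False},
            index=pd.Index(dates, name="date"),
        )
        rep = correlate(prof, cov, grouping="both",
                        covariate_cols=["mean_daily_temp"])
        r = dict(zip(rep["group"], rep["r"].abs()))
        assert r["A"] > r["pooled"]
        assert r["B"] > r["pooled"]
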