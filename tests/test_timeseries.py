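"""Temporal machinery: WMA imputation, outliers, harmonic fits, spectra."""

import numpy as np
import pytest

from aerodyn.timeseries import (TimeSeries, WEEKS_PER_YEAR, aggregate_monthly,
                                correct_outliers, cross_correlation_lag,
                                decompose, fit_harmonic, impute_wma,
                                periodogram, phase_lag)

from conftest import make_weekly


class TestImputeWMA:
    def test_weighted_formula(self):
        ts = make_weekly([6.0, 3.0, 2.0, np.nan])
        out = impute_wma(ts)
        assert out.values[3] == pytest.approx(1 + 1 + 1)

    def test_constant_series_invariance(self):
        x = np.full(30, 7.5)
        x[[10, 17, 18, 25]] = np.nan
        out = impute_wma(make_weekly(x))
        assert np.allclose(out.values, 7.5)

    def test_linear_ramp_closed_form(self):
        # (1/6)(t-3) + (1/3)(t-2) + (1/2)(t-1) = t - 5/3
        x = np.arange(40, dtype=float)
        t = 20
        x[t] = np.nan
        out = impute_wma(make_weekly(x))
        assert out.values[t] == pytest.approx(t - 5 / 3, abs=1e-12)

    def test_forward_sweep_chains_imputations(self):
        x = np.full(20, 4.0)
        x[5:9] = np.nan  # later gaps must use earlier imputations
        out = impute_wma(make_weekly(x))
        assert np.allclose(out.values, 4.0)

    def test_observed_points_untouched(self, rng):
        x = rng.normal(size=60)
        x[30] = np.nan
        ts = make_weekly(x)
        out = impute_wma(ts)
        keep = ~np.isnan(x)
        assert np.array_equal(out.values[keep], x[keep])

    def test_leading_missing_backfilled(self):
        x = np.array([np.nan, np.nan, 3.0, 3.0, np.nan, 3.0])
        out = impute_wma(make_weekly(x))
        assert np.allclose(out.values, 3.0)

    def test_unavailable_predecessor_raises(self):
        x = np.array([5.0, np.nan, 4.0, 4.0, 4.0])
        with pytest.raises(ValueError, match="index 1"):
            impute_wma(make_weekly(x))


class TestCorrectOutliers:
    def test_clean_series_untouched(self):
        ts = make_weekly(np.sin(2 * np.pi * np.arange(60) / 52))
        out, replaced = correct_outliers(ts, k=5.0)
        assert replaced == []
        assert np.array_equal(out.values, ts.values)

    def test_injected_spike_replaced_with_wma(self, rng):
        x = np.sin(2 * np.pi * np.arange(80) / 52) + 0.05 * rng.normal(size=80)
        x[40] += 10.0
        ts = make_weekly(x)
        out, replaced = correct_outliers(ts, k=4.0)
        assert replaced == [40]
        expected = x[37] / 6 + x[38] / 3 + x[39] / 2
        assert out.values[40] == pytest.approx(expected)


class TestFitHarmonic:
    def test_exact_recovery(self, annual_sine):
        fit = fit_harmonic(annual_sine)
        assert fit.a == pytest.approx(2.0, abs=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.amplitude ** 2 == pytest.approx(fit.a ** 2 + fit.b ** 2,
                                                   abs=1e-9)

    def test_intercept_absorbs_mean(self, annual_sine):
        shifted = annual_sine.copy_with(annual_sine.values + 40.0)
        fit = fit_harmonic(shifted)
        assert fit.c == pytest.approx(40.0, abs=1e-8)
        assert fit.a == pytest.approx(2.0, abs=1e-8)

    def test_residuals_orthogonal_to_regressors(self, rng):
        ts = make_weekly(rng.normal(size=157) + np.cos(2 * np.pi *
                                                       np.arange(157) * 7 / 365.25))
        fit = fit_harmonic(ts)
        t = ts.t_years
        resid = ts.values - (fit.a * np.sin(2 * np.pi * t)
                             + fit.b * np.cos(2 * np.pi * t) + fit.c)
        n = len(ts)
        assert abs(resid @ np.sin(2 * np.pi * t)) < 1e-6 * n
        assert abs(resid @ np.cos(2 * np.pi * t)) < 1e-6 * n

    def test_white_noise_rarely_significant(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            fit = fit_harmonic(make_weekly(r.normal(size=156)))
            hits += fit.pvalue >= 0.05 and fit.r2 < 0.15
        assert hits >= 0.9 * n_seeds

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            fit_harmonic(make_weekly(np.ones(30)))


class TestPhaseLag:
    def test_identical_fits_zero(self, annual_sine):
        fit = fit_harmonic(annual_sine)
        assert phase_lag(fit, fit) == pytest.approx(0.0, abs=1e-12)

    def test_sine_vs_cosine_quarter_period(self, annual_sine):
        sine = fit_harmonic(annual_sine)
        cosine = fit_harmonic(annual_sine.copy_with(
            2.0 * np.cos(2 * np.pi * annual_sine.t_years)))
        # sine peaks a quarter year after cosine
        assert phase_lag(sine, cosine) == pytest.approx(WEEKS_PER_YEAR / 4,
                                                        abs=0.05)

    def test_antisymmetry(self, annual_sine, rng):
        t = annual_sine.t_years
        f1 = fit_harmonic(annual_sine.copy_with(
            1.3 * np.sin(2 * np.pi * t) - 0.4 * np.cos(2 * np.pi * t)))
        f2 = fit_harmonic(annual_sine.copy_with(
            0.2 * np.sin(2 * np.pi * t) + 0.9 * np.cos(2 * np.pi * t)))
        assert phase_lag(f1, f2) == pytest.approx(-phase_lag(f2, f1), abs=1e-9)

    def test_known_shift_recovered(self, annual_sine):
        t = annual_sine.t_years
        shift = 4.0 / WEEKS_PER_YEAR
        lagged = annual_sine.copy_with(2.0 * np.sin(2 * np.pi * (t - shift)))
        fit0 = fit_harmonic(annual_sine)
        fit1 = fit_harmonic(lagged)
        assert phase_lag(fit1, fit0) == pytest.approx(4.0, abs=0.01)

    def test_zero_amplitude_rejected(self, annual_sine):
        flat = fit_harmonic(annual_sine.copy_with(
            np.full(len(annual_sine), 3.0)))
        with pytest.raises(ValueError, match="amplitude"):
            phase_lag(flat, fit_harmonic(annual_sine))


class TestPeriodogram:
    def test_annual_tone_dominates(self, annual_sine):
        spec = periodogram(annual_sine)
        assert spec.dominant_period == pytest.approx(1.0, rel=0.05)
        assert (spec.power >= 0).all()

    def test_two_tone_larger_wins(self, annual_sine):
        t = annual_sine.t_years
        y = 2.0 * np.sin(2 * np.pi * t) + 0.8 * np.sin(4 * np.pi * t)
        spec = periodogram(annual_sine.copy_with(y))
        assert spec.dominant_period == pytest.approx(1.0, rel=0.05)

    def test_parseval(self, rng):
        ts = make_weekly(rng.normal(size=156))
        spec = periodogram(ts)
        df = np.diff(spec.frequencies).mean()
        total_power = spec.power.sum() * df
        assert total_power == pytest.approx(ts.values.var(), rel=0.05)

    def test_white_noise_no_dominant_line(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(1000 + seed)
            spec = periodogram(make_weekly(r.normal(size=156)))
            hits += spec.power.max() / spec.power.sum() <= 0.20
        assert hits >= 0.9 * n_seeds


class TestDecompose:
    def test_additivity_and_centering(self, rng):
        x = (np.arange(156) * 0.01
             + np.sin(2 * np.pi * np.arange(156) / 52)
             + 0.2 * rng.normal(size=156))
        ts = make_weekly(x)
        trend, seasonal, resid = decompose(ts, period=52)
        ok = ~np.isnan(trend.values)
        recon = trend.values[ok] + seasonal.values[ok] + resid.values[ok]
        assert np.max(np.abs(recon - x[ok])) < 1e-9
        assert abs(seasonal.values[:52].sum()) < 1e-9

    def test_noiseless_harmonic_with_trend(self):
        x = 0.02 * np.arange(208) + np.sin(2 * np.pi * np.arange(208) / 52)
        trend, seasonal, resid = decompose(make_weekly(x), period=52)
        core = resid.values[52:-52]
        assert np.nanmax(np.abs(core)) < 1e-6


class TestAggregateMonthly:
    def test_constant_series(self):
        ts = make_weekly(np.full(157, 2.5))
        prof = aggregate_monthly(ts)
        assert np.allclose(prof["mean"], 2.5)

    def test_winter_peaking_series_trough_in_summer(self):
        t = make_weekly(np.zeros(157)).t_years
        ts = make_weekly(np.cos(2 * np.pi * (t - 0.04)))  # mid-January peak
        prof = aggregate_monthly(ts)
        assert prof["mean"].idxmin() in (6, 7, 8)
        assert prof["mean"].idxmax() in (12, 1, 2)


class TestCrossCorrelationLag:
    def test_shifted_copy(self, rng):
        x = rng.normal(size=150).cumsum()
        tau = 4
        y = np.roll(x, tau)
        tsx, tsy = make_weekly(x), make_weekly(y)
        lag, r = cross_correlation_lag(tsx, tsy, max_lag=10)
        assert lag == tau
        assert r > 0.9

    def test_cadence_mismatch_rejected(self, rng):
        x = make_weekly(rng.normal(size=100))
        y = TimeSeries("2019-01-01", 1.0, rng.normal(size=100))
        with pytest.raises(ValueError):
            cross_correlation_lag(x, y)
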