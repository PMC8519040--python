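"""Tests for the regression machinery behind the seasonal calibrations."""

import numpy as np
import pytest
import statsmodels.api as sm

import isomilk as im
from isomilk.errors import (
    IncompleteDesignError,
    InsufficientDataError,
    SingularFitError,
    WindowTooSmallError,
)
from isomilk.synthetic import SyntheticHerdConfig, simulate_herd_year


def _ols_oracle(x, y, degree=1):
    """Independent normal-equations fit via statsmodels."""
    X = np.vander(np.asarray(x, float), degree + 1, increasing=True)
    return sm.OLS(np.asarray(y, float), X).fit()


class TestWaterLine:
    def test_exact_line_recovered(self):
        x = np.arange(-12.0, -6.0, 0.5)
        fit = im.fit_water_line(list(zip(x, 8.0 * x + 10.0)))
        assert fit.slope == pytest.approx(8.0, abs=1e-12)
        assert fit.intercept == pytest.approx(10.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.s_yx == pytest.approx(0.0, abs=1e-10)

    def test_three_point_fit_matches_normal_equations(self):
        pts = [(0.0, 0.0), (1.0, 8.0), (2.0, 17.0)]
        fit = im.fit_water_line(pts)
        res = _ols_oracle([p[0] for p in pts], [p[1] for p in pts])
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
        assert fit.slope_se == pytest.approx(res.bse[1], rel=1e-8)
        assert fit.intercept_se == pytest.approx(res.bse[0], rel=1e-8)
        assert fit.s_yx == pytest.approx(np.sqrt(res.mse_resid), rel=1e-10)

    def test_recovers_regional_water_line_parameters(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(-11.4, -7.8, 60)
        y = 8.33 * x + 16.3 + rng.normal(0, 1.6, 60)
        fit = im.fit_water_line(list(zip(x, y)))
        assert abs(fit.slope - 8.33) < 3 * fit.slope_se
        assert abs(fit.intercept - 16.3) < 3 * fit.intercept_se

    def test_degenerate_inputs(self):
        with pytest.raises(SingularFitError):
            im.fit_water_line([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
        with pytest.raises(InsufficientDataError):
            im.fit_water_line([(0.0, 0.0), (1.0, 8.0)])


class TestQuarticFit:
    def test_exact_quartic_interpolated(self):
        true = (2e-9, -1e-6, 3e-4, -1.5e-2, -8.0)
        ts = np.array([10, 80, 150, 220, 290, 360], dtype=float)
        ys = np.polyval(true, ts)
        fit = im.fit_quartic(ts, ys)
        grid = np.arange(1, 366)
        assert np.allclose(fit.predict(grid), np.polyval(true, grid), atol=1e-8)
        assert fit.s_yx == pytest.approx(0.0, abs=1e-8)

    def test_constant_target_collapses_to_mean(self):
        ts = np.linspace(10, 360, 12)
        fit = im.fit_quartic(ts, np.full(12, 3.7))
        assert np.allclose(fit.coefficients[:4], 0.0, atol=1e-12)
        assert fit.coefficients[4] == pytest.approx(3.7)

    def test_matches_normal_equations_oracle(self):
        # compare fitted values (well-conditioned) rather than raw-power
        # coefficients, whose Vandermonde conditioning limits any solver
        rng = np.random.default_rng(7)
        for _ in range(5):
            ts = rng.uniform(1, 365, 20)
            ys = rng.normal(-8.0, 1.0, 20)
            fit = im.fit_quartic(ts, ys)
            res = _ols_oracle(ts / 365.0, ys, degree=4)
            assert np.allclose(fit.predict(ts), res.fittedvalues, rtol=1e-8)
            assert fit.s_yx == pytest.approx(np.sqrt(res.mse_resid), rel=1e-8)

    def test_recovers_generating_curve_within_band(self, eq5):
        # monthly survey design: 7 sheds sampled on day 15 of each month
        rng = np.random.default_rng(11)
        ts = np.tile(np.arange(15, 366, 30), 7).astype(float)
        ys = eq5.predict(ts) + rng.normal(0, 0.92, ts.size)
        fit = im.fit_quartic(ts, ys)
        grid = np.arange(1, 366)
        assert np.all(
            np.abs(fit.predict(grid) - eq5.predict(grid)) <= 1.645 * fit.s_yx
        )

    def test_exclusion_by_shed_label(self):
        ts = np.tile(np.linspace(10, 360, 8), 2)
        ys = np.concatenate([np.zeros(8), np.full(8, 100.0)])
        sheds = ["in"] * 8 + ["out"] * 8
        fit = im.fit_quartic(ts, ys, shed_ids=sheds, exclude=["out"])
        assert fit.n == 8
        assert np.allclose(fit.predict([50, 200]), 0.0, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(SingularFitError):
            im.fit_quartic([10, 10, 20, 20, 30, 30], np.arange(6.0))
        with pytest.raises(InsufficientDataError):
            im.fit_quartic([1, 2, 3, 4, 5], np.arange(5.0))

    def test_alpha_target_scales_syx_to_permil(self):
        rng = np.random.default_rng(3)
        ts = rng.uniform(1, 365, 30)
        ys = 1.0012 + rng.normal(0, 4e-4, 30)
        fit = im.fit_quartic(ts, ys, target="alpha")
        assert 0.1 < fit.s_yx < 1.0  # ≈0.4‰, not ≈4e-4


class TestLoess:
    def test_reproduces_exact_line(self):
        ts = np.linspace(1, 365, 40)
        ys = 0.01 * ts - 8.0
        grid, smoothed = im.loess_smooth(ts, ys, span=0.4, grid=ts)
        assert np.allclose(smoothed, ys, atol=1e-8)

    def test_full_span_equals_global_line_on_linear_data(self):
        ts = np.linspace(1, 365, 30)
        ys = 0.004 * ts - 7.5
        _, smoothed = im.loess_smooth(ts, ys, span=1.0, grid=ts)
        fit = im.fit_water_line(list(zip(ts, ys)))
        assert np.allclose(smoothed, fit.predict(ts), atol=1e-8)

    def test_tracks_quartic_like_polynomial_fit(self, eq5):
        # the smoother and the quartic describe seasonal data near-identically
        rng = np.random.default_rng(5)
        ts = np.sort(rng.uniform(1, 365, 84))
        ys = eq5.predict(ts) + rng.normal(0, 0.92, 84)
        fit = im.fit_quartic(ts, ys)
        grid = np.linspace(20, 346, 50)
        _, smoothed = im.loess_smooth(ts, ys, span=0.2, grid=grid)
        rms = np.sqrt(np.mean((smoothed - fit.predict(grid)) ** 2))
        assert rms < fit.s_yx

    def test_window_and_size_guards(self):
        ts = np.linspace(1, 100, 12)
        with pytest.raises(WindowTooSmallError):
            im.loess_smooth(ts, ts, span=0.1)
        with pytest.raises(InsufficientDataError):
            im.loess_smooth(ts[:8], ts[:8])


class TestSeasonalPredictions:
    @pytest.mark.parametrize("t, expected", [(20, -8.11), (36, -8.13), (358, -8.21)])
    def test_milk_delta_at_known_days(self, eq5, t, expected):
        assert round(im.predict_milk_delta(t, eq5).value, 2) == expected

    def test_constant_term_is_winter_baseline(self, eq5, eq6b):
        assert float(eq5.predict(0)) == pytest.approx(-7.91)
        assert float(eq6b.predict(0)) == pytest.approx(1.0012)

    def test_bands(self, eq5):
        pred = im.predict_milk_delta(100, eq5)
        assert pred.band_1s == pytest.approx(
            (pred.value - 0.92, pred.value + 0.92)
        )
        assert pred.band_coverage == pytest.approx(
            (pred.value - 1.645 * 0.92, pred.value + 1.645 * 0.92)
        )

    @pytest.mark.parametrize(
        "t, expected", [(20, 1.001036), (36, 1.001058), (150, 1.002534), (358, 1.001096)]
    )
    def test_alpha_at_known_days(self, eq6b, t, expected):
        assert round(im.predict_alpha(t, eq6b).alpha, 6) == expected

    def test_day_number_domain_enforced(self, eq5, eq6b):
        with pytest.raises(ValueError):
            im.predict_milk_delta(0, eq5)
        with pytest.raises(ValueError):
            im.predict_alpha(366, eq6b)

    def test_horner_and_naive_evaluation_agree(self, eq5, eq6b):
        for calib in (eq5, eq6b):
            c = calib.coefficients
            for t in (1, 36, 150, 222, 358, 365):
                naive = sum(c[4 - k] * t**k for k in range(5))
                assert float(calib.predict(t)) == pytest.approx(naive, rel=1e-12)


class TestAlphaPredictionUncertainty:
    def test_matches_published_constants_within_rounding(self):
        u_all = im.alpha_prediction_uncertainty(
            im.QuarticCalibration("x", "alpha", (0, 0, 0, 0, 1.0), n=108, s_yx=0.50)
        )
        u_indoor = im.alpha_prediction_uncertainty(
            im.QuarticCalibration("x", "alpha", (0, 0, 0, 0, 1.0), n=84, s_yx=0.41)
        )
        assert u_all == pytest.approx(0.5023, abs=5e-4)
        assert abs(u_all - 0.51) < 0.01
        assert u_indoor == pytest.approx(0.4124, abs=5e-4)
        assert abs(u_indoor - 0.42) < 0.01

    def test_zero_scatter_gives_zero(self):
        calib = im.QuarticCalibration("x", "alpha", (0, 0, 0, 0, 1.0), n=50, s_yx=0.0)
        assert im.alpha_prediction_uncertainty(calib) == 0.0

    def test_bundled_overrides_take_precedence(self, eq6a, eq6b):
        assert im.alpha_prediction_uncertainty(eq6a) == 0.51
        assert im.alpha_prediction_uncertainty(eq6b) == 0.42


class TestAlphaVsTemperature:
    def test_exact_linear_response_recovered(self):
        records = []
        for i, temp in enumerate([2.0, 8.0, 14.0, 20.0, 26.0]):
            alpha = 7e-5 * temp + 1.0005
            w = -9.0
            m = im.milk_delta_from_alpha(alpha, w)
            records.append(
                im.SampleRecord("A", t=30 * (i + 1), d18O_W=w, d18O_M=m, temp_2wk=temp)
            )
        reg = im.fit_alpha_vs_temperature(records)
        assert reg.slope == pytest.approx(7e-5, rel=1e-6)
        assert reg.r == pytest.approx(1.0)

    def test_slope_recovered_within_two_se(self):
        config = SyntheticHerdConfig(
            n_sheds=1, seed=21, alpha_temp_slope_range=(6.9e-5, 6.9e-5)
        )
        reg = im.fit_alpha_vs_temperature(simulate_herd_year(config))
        assert abs(reg.slope - 6.9e-5) < 2 * reg.slope_se
        assert reg.r > 0.5

    def test_outdoor_shed_has_steeper_response(self):
        base = dict(n_sheds=1, seed=33, alpha_temp_slope_range=(6.9e-5, 6.9e-5))
        indoor = im.fit_alpha_vs_temperature(
            simulate_herd_year(SyntheticHerdConfig(**base))
        )
        outdoor = im.fit_alpha_vs_temperature(
            simulate_herd_year(
                SyntheticHerdConfig(**base, outdoor_sheds=("shed01",))
            )
        )
        assert outdoor.slope > indoor.slope

    def test_missing_temperatures_skipped_or_fatal(self):
        good = [
            im.SampleRecord("A", t=30 * (i + 1), d18O_W=-9.0, d18O_M=-7.5, temp_2wk=float(i))
            for i in range(4)
        ]
        holed = good + [im.SampleRecord("A", t=200, d18O_W=-9.0, d18O_M=-7.5)]
        assert im.fit_alpha_vs_temperature(holed).n_skipped == 1
        with pytest.raises(InsufficientDataError):
            im.fit_alpha_vs_temperature(
                [im.SampleRecord("A", t=10, d18O_W=-9.0, d18O_M=-7.5)] * 5
            )


class TestTwoWayAnova:
    def test_identical_rows_have_zero_time_component(self):
        m = np.tile([1.0, 2.0, 3.0], (4, 1)).T  # every row identical
        table = im.two_way_anova(np.tile([1.0, 2.0, 3.0], (4, 1)))
        assert table.ss_rows == pytest.approx(0.0, abs=1e-12)

    def test_three_by_three_matches_bruteforce_decomposition(self):
        m = np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 5.0], [6.0, 7.0, 10.0]])
        table = im.two_way_anova(m)
        # brute-force sums of squares
        grand = m.mean()
        ss_rows = sum(3 * (row.mean() - grand) ** 2 for row in m)
        ss_cols = sum(3 * (col.mean() - grand) ** 2 for col in m.T)
        ss_total = ((m - grand) ** 2).sum()
        assert table.ss_rows == pytest.approx(ss_rows)
        assert table.ss_cols == pytest.approx(ss_cols)
        assert table.ss_error == pytest.approx(ss_total - ss_rows - ss_cols)
        assert table.df_rows == 2 and table.df_cols == 2 and table.df_error == 4

    def test_additivity_and_shift_invariance(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(12, 9))
        t1 = im.two_way_anova(m)
        assert t1.ss_rows + t1.ss_cols + t1.ss_error == pytest.approx(
            ((m - m.mean()) ** 2).sum(), rel=1e-10
        )
        t2 = im.two_way_anova(m + 17.3)
        for attr in ("ms_rows", "ms_cols", "ms_error"):
            assert getattr(t1, attr) == pytest.approx(getattr(t2, attr), rel=1e-9)

    def test_seasonal_signal_dominates_shed_signal(self):
        records = simulate_herd_year(SyntheticHerdConfig(seed=2))
        sheds = sorted({r.shed_id for r in records})
        months = list(range(1, 13))
        matrix = np.array(
            [
                [
                    next(
                        im.compute_alpha(r.d18O_M, r.d18O_W).alpha
                        for r in records
                        if r.shed_id == s and r.month == mo
                    )
                    for s in sheds
                ]
                for mo in months
            ]
        )
        table = im.two_way_anova(matrix)
        assert table.ms_rows > table.ms_cols > table.ms_error

    def test_missing_cells_rejected(self):
        m = np.ones((3, 3))
        m[1, 1] = np.nan
        with pytest.raises(IncompleteDesignError):
            im.two_way_anova(m)
        with pytest.raises(IncompleteDesignError):
            im.two_way_anova(np.ones((1, 5)))


class TestDexTemperatureCorrelation:
    def test_temperature_driven_enrichment_correlates(self):
        records = simulate_herd_year(SyntheticHerdConfig(seed=1))
        assert im.dex_temperature_correlation(records) > 0.7

    def test_null_enrichment_uncorrelated(self):
        config = SyntheticHerdConfig(
            seed=1, alpha_temp_slope_range=(0.0, 1e-9), dex_temp_slope=0.0
        )
        assert abs(im.dex_temperature_correlation(simulate_herd_year(config))) < 0.3

    def test_constant_temperature_not_computable(self):
        records = [
            im.SampleRecord(
                "A", t=30 * (i + 1), d18O_W=-9.0, d2H_W=-60.0,
                d18O_M=-7.0 + 0.1 * i, d2H_M=-50.0 + i, temp_2wk=12.0,
            )
            for i in range(5)
        ]
        assert np.isnan(im.dex_temperature_correlation(records))

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            im.dex_temperature_correlation(
                [im.SampleRecord("A", t=10, d18O_W=-9.0, d2H_W=-60.0,
                                 d18O_M=-7.0, d2H_M=-50.0, temp_2wk=5.0)]
            )


def _period_records(warm_shift=0.0, warm_slope=None, noise=0.0, seed=0):
    """Sheds with one cold and one warm observation each, on known lines."""
    rng = np.random.default_rng(seed)
    records = []
    for i, w in enumerate(np.linspace(-11.0, -8.0, 6)):
        slope_w = 0.774 if warm_slope is None else warm_slope
        cold_m = 0.774 * w - 1.14 + rng.normal(0, noise)
        warm_m = slope_w * w - 1.14 + warm_shift + rng.normal(0, noise)
        records.append(
            im.SampleRecord(f"s{i}", t=15, d18O_W=w, d18O_M=cold_m)  # January
        )
        records.append(
            im.SampleRecord(f"s{i}", t=196, d18O_W=w, d18O_M=warm_m)  # July
        )
    return records


class TestPeriodicRegressions:
    def test_identical_periods_have_equal_slopes(self):
        cmp = im.periodic_regressions(_period_records(noise=0.0))
        assert cmp.cold.slope == pytest.approx(cmp.warm.slope, abs=1e-9)
        assert cmp.p_same_slope > 0.5

    def test_parallel_shift_detected_as_intercept_difference(self):
        cmp = im.periodic_regressions(_period_records(warm_shift=1.4, noise=0.05, seed=2))
        assert cmp.p_same_slope > 0.05
        assert cmp.intercept_difference == pytest.approx(1.4, abs=0.5)

    def test_different_slopes_detected(self):
        cmp = im.periodic_regressions(
            _period_records(warm_slope=1.3, noise=0.02, seed=3)
        )
        assert cmp.p_same_slope < 0.01

    def test_sparse_period_rejected(self):
        records = _period_records()[:4]  # only 2 sheds
        with pytest.raises(InsufficientDataError):
            im.periodic_regressions(records)


class TestCalibrationFiles:
    def test_bundled_calibrations_load(self, eq5, eq6a, eq6b):
        assert eq5.n == 84 and eq5.s_yx == 0.92 and eq5.target == "milk_d18O"
        assert eq6a.n == 108 and eq6a.s_yx == 0.50 and eq6a.u_pred == 0.51
        assert eq6b.n == 84 and eq6b.s_yx == 0.41 and eq6b.u_pred == 0.42
        assert eq6b.excluded_sheds == ("Castelnovo", "Baiso")

    def test_save_load_round_trip(self, tmp_path, eq6b):
        path = tmp_path / "calib.yaml"
        im.save_calibration(eq6b, str(path))
        loaded = im.load_calibration(str(path))
        assert loaded == eq6b
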