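import numpy as np
import pytest

import richfit as rf
from richfit.fitting import FitConfig, ModelKind, _predict


class TestInitGuess:
    def test_half_max_crossing_near_truth(self):
        p = rf.FourPLParams(0.0, 1.0, 1.0, np.log(1e-8))
        conc = np.logspace(-11, -5, 15)
        series = rf.TitrationSeries(conc, rf.fourpl_value(np.log(conc), p))
        guess = rf.init_guess(series, ModelKind.FOURPL)
        assert abs(guess.log_infl - np.log(1e-8)) <= 0.5

    def test_flat_series_rejected(self):
        series = rf.TitrationSeries(np.logspace(-10, -6, 8), np.full(8, 42.0))
        with pytest.raises(ValueError, match="no dynamic range"):
            rf.init_guess(series, ModelKind.GL)

    def test_descending_series_rejected(self):
        conc = np.logspace(-10, -6, 8)
        series = rf.TitrationSeries(conc, np.linspace(100.0, 1.0, 8))
        with pytest.raises(ValueError, match="non-increasing trend"):
            rf.init_guess(series, ModelKind.GL)


class TestFitModel:
    def test_noiseless_gl_recovery(self, gl_series):
        series, p = gl_series(s_span=1000.0, rate=1.2, log_infl=np.log(5e-9), nu=0.5)
        fit = rf.fit_model(series, ModelKind.GL)
        assert fit.converged
        truth = np.array([p.s_floor, p.s_span, p.rate, p.log_infl, p.nu])
        scale = np.where(np.abs(truth) > 1e-9, np.abs(truth), p.s_span)
        assert np.max(np.abs(fit.theta - truth) / scale) <= 1e-4

    @pytest.mark.parametrize("rate", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("nu", [0.2, 0.5, 1.0, 2.0, 5.0])
    def test_recovery_across_parameter_grid(self, gl_series, rate, nu):
        series, p = gl_series(s_floor=5.0, rate=rate, nu=nu, n=14)
        fit = rf.fit_model(series, ModelKind.GL)
        truth = np.array([p.s_floor, p.s_span, p.rate, p.log_infl, p.nu])
        assert np.max(np.abs(fit.theta - truth) / np.abs(truth)) <= 1e-3

    def test_symmetric_data_recovers_unit_nu(self, fourpl_series):
        series, _ = fourpl_series
        fit = rf.fit_model(series, ModelKind.GL)
        assert 0.95 <= fit.params.nu <= 1.05

    def test_noisy_log_infl_recovery(self):
        # multiplicative 5% noise, 3 replicates: the inflection stays
        # well-determined (light version of the full simulation study)
        true_kd = 1e-8
        mix = rf.ClonalMixture([rf.Clone(true_kd, 1e-10)])
        grid = rf.log_conc_grid(true_kd, 3, 12)
        errs = []
        for seed in range(30):
            assay = rf.AssayConfig(
                conc_grid=grid, noise_cv=0.05, replicates=3,
                signal_per_bound=1e12, seed=seed,
            )
            fit = rf.fit_model(rf.simulate_titration(mix, assay), ModelKind.GL)
            errs.append(abs(fit.params.log_infl - np.log(true_kd)))
        assert np.median(errs) <= 0.15

    def test_under_determined_rejected(self):
        conc = np.logspace(-10, -6, 5)
        y = rf.gl_value(np.log(conc), rf.GLParams(0, 1, 1, np.log(1e-8), 1))
        series = rf.TitrationSeries(conc, y)
        with pytest.raises(ValueError, match="under-determined"):
            rf.fit_model(series, ModelKind.GL)

    def test_refit_is_stable(self, gl_series):
        series, _ = gl_series(nu=0.3)
        fit = rf.fit_model(series, ModelKind.GL)
        refit = rf.fit_model(series, ModelKind.GL)
        assert abs(refit.rss - fit.rss) <= 1e-10 * max(fit.rss, 1e-30)

    def test_scale_equivariance(self, gl_series):
        series, _ = gl_series(s_floor=2.0, s_span=500.0, nu=0.5)
        k = 7.5
        scaled = rf.TitrationSeries(series.conc, k * series.signal)
        f1 = rf.fit_model(series, ModelKind.GL)
        f2 = rf.fit_model(scaled, ModelKind.GL)
        assert np.max(np.abs(f2.theta[2:] - f1.theta[2:])) <= 1e-8
        assert f2.theta[0] == pytest.approx(k * f1.theta[0], abs=1e-8 * f1.theta[1])
        assert f2.theta[1] == pytest.approx(k * f1.theta[1], rel=1e-8)

    def test_reparameterization_equivalence(self, fourpl_series):
        # the Hill (b, c_mid) parameterization is the 5PL with g pinned at 1;
        # both routes must reproduce the same predicted curve
        series, _ = fourpl_series
        f4 = rf.fit_model(series, ModelKind.FOURPL)
        f5 = rf.fit_model(
            series,
            ModelKind.FIVEPL,
            FitConfig(bounds_overrides={"asym_g": (1 - 1e-9, 1 + 1e-9)}),
        )
        xg = np.linspace(series.log_conc[0], series.log_conc[-1], 40)
        diff = _predict(ModelKind.FOURPL, f4.theta, xg) - _predict(
            ModelKind.FIVEPL, f5.theta, xg
        )
        assert np.max(np.abs(diff)) <= 1e-8 * f4.params.s_span

    def test_replicates_enter_as_independent_observations(self, gl_series):
        series, _ = gl_series()
        signal2 = np.column_stack([series.signal, series.signal])
        rep = rf.TitrationSeries(series.conc, signal2)
        fit = rf.fit_model(rep, ModelKind.GL)
        assert fit.n_obs == 2 * series.n_conc
        assert fit.converged

    def test_relative_weighting_fits(self):
        mix = rf.ClonalMixture([rf.Clone(1e-8, 1e-10)])
        assay = rf.AssayConfig(
            conc_grid=rf.log_conc_grid(1e-8, 3, 12), noise_cv=0.1,
            replicates=2, signal_per_bound=1e12, seed=5,
        )
        series = rf.simulate_titration(mix, assay)
        fit = rf.fit_model(series, ModelKind.GL, FitConfig(weighting="relative"))
        assert fit.converged
        assert abs(fit.params.log_infl - np.log(1e-8)) < 0.5


class TestCompareModels:
    def test_symmetric_data_prefers_fourpl(self, fourpl_series):
        series, _ = fourpl_series
        comparison = rf.compare_models(series)
        aic = {f.model: f.aic for f in comparison.ranked}
        assert aic[ModelKind.FOURPL] <= aic[ModelKind.GL]

    def test_asymmetric_data_needs_gl(self, gl_series):
        series, _ = gl_series(nu=0.1)
        comparison = rf.compare_models(series)
        rss = {f.model: f.rss for f in comparison.ranked}
        assert rss[ModelKind.GL] < rss[ModelKind.FOURPL]

    def test_five_point_series_fails_only_five_param_models(self):
        conc = np.logspace(-10.5, -5.5, 5)
        y = rf.fourpl_value(np.log(conc), rf.FourPLParams(0.0, 1.0, 1.0, np.log(1e-8)))
        series = rf.TitrationSeries(conc, y)
        comparison = rf.compare_models(series)
        fitted = {f.model for f in comparison.ranked}
        assert ModelKind.FOURPL in fitted
        assert ModelKind.FIVEPL in comparison.errors
        assert "under-determined" in comparison.errors[ModelKind.FIVEPL]

    def test_aic_differences_invariant_to_rescaling(self):
        mix = rf.ClonalMixture([rf.Clone(1e-8, 1e-10)])
        assay = rf.AssayConfig(
            conc_grid=rf.log_conc_grid(1e-8, 3, 12), noise_cv=0.05,
            replicates=2, signal_per_bound=1e12, seed=11,
        )
        series = rf.simulate_titration(mix, assay)
        scaled = rf.TitrationSeries(series.conc, 3.7 * series.signal)
        a1 = {f.model: f.aic for f in rf.compare_models(series).ranked}
        a2 = {f.model: f.aic for f in rf.compare_models(scaled).ranked}
        n = series.y_flat.size
        shift = n * np.log(3.7**2)
        for m in a1:
            assert a2[m] - a1[m] == pytest.approx(shift, abs=1e-6)

    def test_delta_aic_and_ties(self, fourpl_series):
        series, _ = fourpl_series
        comparison = rf.compare_models(series)
        assert comparison.delta_aic[0] == 0.0
        assert np.all(np.diff(comparison.delta_aic) >= 0)
        assert bool(comparison.indistinguishable_from_best[0])


class TestBootstrap:
    def test_noiseless_intervals_degenerate(self, gl_series):
        series, _ = gl_series(nu=0.5)
        fit = rf.fit_model(series, ModelKind.GL)
        ci = rf.bootstrap_ci(series, fit, FitConfig(bootstrap_n=100, seed=1))
        width = ci.hi - ci.lo
        scale = np.maximum(np.abs(fit.theta), 1.0)
        assert np.all(width / scale <= 1e-6)
        assert np.all(ci.lo <= fit.theta + 1e-12)
        assert np.all(ci.hi >= fit.theta - 1e-12)

    def test_seed_reproducibility(self):
        mix = rf.ClonalMixture([rf.Clone(1e-8, 1e-10)])
        assay = rf.AssayConfig(
            conc_grid=rf.log_conc_grid(1e-8, 3, 12), noise_cv=0.05,
            replicates=3, signal_per_bound=1e12, seed=3,
        )
        series = rf.simulate_titration(mix, assay)
        fit = rf.fit_model(series, ModelKind.GL)
        cfg = FitConfig(bootstrap_n=100, seed=9)
        ci1 = rf.bootstrap_ci(series, fit, cfg)
        ci2 = rf.bootstrap_ci(series, fit, cfg)
        np.testing.assert_array_equal(ci1.samples, ci2.samples)
        np.testing.assert_array_equal(ci1.lo, ci2.lo)

    def test_requires_converged_fit_and_enough_resamples(self, gl_series):
        series, _ = gl_series()
        fit = rf.fit_model(series, ModelKind.GL)
        from dataclasses import replace

        with pytest.raises(ValueError):
            rf.bootstrap_ci(series, replace(fit, converged=False), FitConfig(bootstrap_n=100))
        with pytest.raises(ValueError):
            rf.bootstrap_ci(series, fit, FitConfig(bootstrap_n=50))
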