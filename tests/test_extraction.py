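"""Extractor correctness: closed-form oracles, round trips, invariances."""
import numpy as np
import pytest

from phenoflux import extraction, synthetic
from phenoflux.curves import INFLECTION_OFFSET, double_logistic
from phenoflux.errors import (ConfigError, GapError, NoSeasonalityError)
from phenoflux.extraction import (DoubleLogisticParams, ImageColorMeans,
                                  carbon_metrics, extract_sos_eos_from_fit,
                                  fit_double_logistic, gcc, gcc_sos, gpp_sos,
                                  savitzky_golay, ssa_smooth)
from phenoflux.series import DailySeries


def _series(values, year=2000, doy=None, var="x"):
    values = np.asarray(values, float)
    doy = np.arange(1, values.size + 1) if doy is None else np.asarray(doy)
    return DailySeries("S", var, np.full(values.size, year), doy, values)


class TestGcc:
    def test_pure_green(self):
        assert gcc(ImageColorMeans(0, 255, 0)) == 1.0

    def test_grey_is_one_third(self):
        assert gcc(ImageColorMeans(100, 100, 100)) == pytest.approx(1 / 3)

    def test_direct_arithmetic(self):
        assert gcc(ImageColorMeans(50, 100, 50)) == 0.5

    def test_all_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            gcc(ImageColorMeans(0, 0, 0))


class TestGccSos:
    def test_step_curve_crossing_day(self):
        vals = np.where(np.arange(1, 366) < 140, 0.30, 0.45)
        assert gcc_sos(_series(vals), 2000) == 140

    def test_constant_curve_has_no_seasonality(self):
        with pytest.raises(NoSeasonalityError):
            gcc_sos(_series(np.full(365, 0.35)), 2000)

    def test_half_amplitude_crossing_matches_inflection(self, quiet_truth):
        c = synthetic.generate_seasonal_curve(quiet_truth[0], "gcc",
                                              obs_noise_sd=0.0, seed=0)
        assert abs(gcc_sos(c, quiet_truth[0].year) - 120) <= 2

    def test_shift_equivariance(self, site, quiet_temp):
        base = synthetic.generate_phenology_truth(
            site, quiet_temp, base_sos=120, true_st=0, sos_noise_sd=0,
            seed=0)[0]
        shifted = synthetic.generate_phenology_truth(
            site, quiet_temp, base_sos=130, true_st=0, sos_noise_sd=0,
            seed=0)[0]
        c0 = synthetic.generate_seasonal_curve(base, "gcc", obs_noise_sd=0,
                                               seed=0)
        c1 = synthetic.generate_seasonal_curve(shifted, "gcc", obs_noise_sd=0,
                                               seed=0)
        assert gcc_sos(c1, base.year) - gcc_sos(c0, base.year) == \
            pytest.approx(10, abs=1)


class TestSavitzkyGolay:
    def test_interpolating_order_reproduces_input(self):
        rng = np.random.default_rng(0)
        s = _series(rng.normal(size=31))
        out = savitzky_golay(s, window=5, polyorder=4)
        np.testing.assert_allclose(out.value, s.value, atol=1e-8)

    def test_cubic_signal_reproduced_exactly(self):
        t = np.arange(1, 51, dtype=float)
        s = _series(1e-4 * t ** 3 - 0.01 * t ** 2 + t)
        out = savitzky_golay(s, window=7, polyorder=3)
        np.testing.assert_allclose(out.value, s.value, atol=1e-9)

    def test_white_noise_variance_contracts(self):
        rng = np.random.default_rng(1)
        s = _series(rng.normal(size=300))
        out = savitzky_golay(s, window=7, polyorder=2)
        assert out.value.var() < s.value.var()

    def test_invalid_window_rejected(self):
        with pytest.raises(ConfigError):
            savitzky_golay(_series(np.arange(20.0)), window=4, polyorder=2)
        with pytest.raises(ConfigError):
            savitzky_golay(_series(np.arange(5.0)), window=7, polyorder=2)


class TestDoubleLogisticFit:
    def test_zero_noise_parameter_recovery(self):
        t = np.arange(1, 366, dtype=float)
        y = double_logistic(t, 0.5, 0.2, 0.1, 120, 0.08, 280)
        params, diag = fit_double_logistic(_series(y), 2000)
        assert diag.converged
        for got, want in [(params.a, 0.5), (params.b, 0.2), (params.k, 0.1),
                          (params.m, 120), (params.r_autumn, 0.08),
                          (params.n, 280)]:
            assert got == pytest.approx(want, rel=1e-3)

    def test_plateau_of_fit_is_amplitude_plus_background(self):
        t = np.arange(1, 366, 15, dtype=float)
        y = double_logistic(t, 0.5, 0.2, 0.1, 120, 0.1, 280)
        params, _ = fit_double_logistic(_series(y, doy=t.astype(int)), 2000)
        assert params.curve(200.0) == pytest.approx(0.7, rel=0.01)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ConfigError):
            fit_double_logistic(_series(np.arange(5.0)), 2000)

    def test_noisy_recovery_median_error_small(self):
        """24 points/year, noise sd 0.02 on amplitude 0.5: the spring
        inflection is recovered to a few days (scaled-down Monte Carlo)."""
        t = np.arange(1, 366, 15, dtype=float)
        clean = double_logistic(t, 0.5, 0.2, 0.1, 120, 0.1, 280)
        errs = []
        rng = np.random.default_rng(7)
        for _ in range(30):
            y = clean + rng.normal(0, 0.02, size=t.size)
            params, diag = fit_double_logistic(_series(y, doy=t.astype(int)),
                                               2000)
            if diag.converged:
                errs.append(abs(params.m - 120))
        assert len(errs) >= 28
        assert np.median(errs) <= 3.0


class TestSecondDerivativeExtraction:
    @pytest.mark.parametrize("k", [0.05, 0.1, 0.2])
    def test_matches_closed_form_inflection_offset(self, k):
        """Numeric curvature maximum vs t = m - ln(2+sqrt(3))/k."""
        params = DoubleLogisticParams(a=0.5, b=0.2, k=k, m=150.0,
                                      r_autumn=k, n=300.0)
        t = np.arange(1, 365.05, 0.1)
        d2 = params.second_derivative(t)
        i = np.argmax(d2[t < 220])
        t_num = t[i]
        t_closed = 150.0 - INFLECTION_OFFSET / k
        assert abs(t_num - t_closed) <= 0.2

    def test_symmetric_curve_gives_symmetric_sos_eos(self):
        params = DoubleLogisticParams(a=0.5, b=0.2, k=0.1, m=120.0,
                                      r_autumn=0.1, n=280.0)
        sos, eos = extract_sos_eos_from_fit(params)
        mid = (120 + 280) / 2
        assert abs((mid - sos) - (eos - mid)) <= 1

    def test_zero_noise_ndvi_round_trip_and_ordering(self, quiet_truth):
        c = synthetic.generate_seasonal_curve(quiet_truth[0], "ndvi",
                                              obs_noise_sd=0.0, seed=0,
                                              cadence_days=1)
        params, _ = fit_double_logistic(c, quiet_truth[0].year)
        sos, eos = extract_sos_eos_from_fit(params)
        assert abs(sos - 120) <= 15 and abs(eos - 280) <= 15
        assert sos < params.m < params.n < eos


class TestSSA:
    def test_full_rank_reconstruction_is_identity(self):
        rng = np.random.default_rng(2)
        s = _series(rng.normal(size=200))
        out = ssa_smooth(s, window_length=20, n_components=20)
        np.testing.assert_allclose(out.value, s.value, atol=1e-8)

    def test_sinusoid_is_rank_two(self):
        t = np.arange(400.0)
        clean = np.sin(2 * np.pi * t / 80)
        out = ssa_smooth(_series(clean[:365]), 60, 2)
        ss_res = np.sum((out.value - clean[:365]) ** 2)
        ss_tot = np.sum((clean[:365] - clean[:365].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_denoising_improves_signal_correlation(self):
        rng = np.random.default_rng(3)
        t = np.arange(365.0)
        clean = np.sin(2 * np.pi * t / 180)
        noisy = clean + rng.normal(0, clean.std() / 5, size=t.size)
        out = ssa_smooth(_series(noisy), 60, 4)
        r_raw = np.corrcoef(noisy, clean)[0, 1]
        r_smooth = np.corrcoef(out.value, clean)[0, 1]
        assert r_smooth > r_raw

    def test_long_gap_rejected(self):
        vals = np.sin(np.arange(365.0) / 30)
        vals[100:140] = np.nan
        with pytest.raises(GapError):
            ssa_smooth(_series(vals), 60, 4)


class TestGppSos:
    def _ramp(self, cross_day, high=10.0):
        vals = np.zeros(365)
        vals[cross_day - 1:] = high * 0.2
        return _series(vals, var="gpp")

    def test_sustained_crossing_day(self):
        s = self._ramp(115)
        assert gpp_sos(s, 2000, multi_year_max=10.0) == 115

    def test_never_exceeding_threshold_flags_no_season(self):
        s = _series(np.full(365, 1.0), var="gpp")
        assert gpp_sos(s, 2000, multi_year_max=10.0) is None

    def test_single_day_spike_excluded_by_persistence(self):
        vals = np.zeros(365)
        vals[79] = 2.0            # spike on doy 80
        vals[119:] = 2.0          # sustained from doy 120
        assert gpp_sos(_series(vals, var="gpp"), 2000, 10.0) == 120

    def test_amplitude_invariance(self):
        vals = np.clip(np.sin((np.arange(1, 366) - 90) / 60), 0, None) * 8
        s1 = _series(vals, var="gpp")
        s5 = _series(5 * vals, var="gpp")
        assert gpp_sos(s1, 2000, 8.0) == gpp_sos(s5, 2000, 40.0)


class TestCarbonMetrics:
    def test_constant_gpp(self):
        cm = carbon_metrics(_series(np.full(365, 5.0), var="gpp"), 2000)
        assert cm.gpp_max == 5.0
        assert cm.gpp_mean_gs == 5.0

    def test_triangular_peak_matches_piecewise_linear_mean(self):
        doy = np.arange(1, 366, dtype=float)
        vals = np.interp(doy, [1, 100, 180, 260, 365], [0, 0, 12, 0, 0])
        cm = carbon_metrics(_series(vals, var="gpp"), 2000)
        assert cm.gpp_max == pytest.approx(12.0, abs=0.1)
        gs = vals[120:273]  # doy 121..273
        assert cm.gpp_mean_gs == pytest.approx(gs.mean())

    def test_april_peak_allows_mean_below_max(self):
        doy = np.arange(1, 366, dtype=float)
        vals = np.interp(doy, [1, 90, 110, 130, 365], [0, 0, 9, 0, 0]) + 1.0
        cm = carbon_metrics(_series(vals, var="gpp"), 2000)
        assert cm.gpp_max == pytest.approx(10.0, abs=0.2)
        assert cm.gpp_mean_gs < cm.gpp_max
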