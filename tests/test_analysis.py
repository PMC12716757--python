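"""Receptive-field estimation, Gabor fits, sparseness, correlations, balance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparsev1 as s
from sparsev1.analysis import BALANCE_CATEGORIES, probe_loose_balance
from sparsev1.errors import ConfigurationError, DegenerateInputError


def synth_gabor(p=16, sigma_x=2.0, sigma_y=3.0, fs=0.15, ori=0.7,
                phase=0.4, amp=1.0, x0=None, y0=None):
    Y, X = np.mgrid[0:p, 0:p].astype(float)
    x0 = p / 2 if x0 is None else x0
    y0 = p / 2 if y0 is None else y0
    dx, dy = X - x0, Y - y0
    xr = dx * np.cos(ori) + dy * np.sin(ori)
    yr = -dx * np.sin(ori) + dy * np.cos(ori)
    env = np.exp(-(xr ** 2 / (2 * sigma_x ** 2) + yr ** 2 / (2 * sigma_y ** 2)))
    return amp * env * np.cos(2 * np.pi * fs * xr + phase)


# -- sparseness ---------------------------------------------------------------

class TestSparseness:
    def test_one_hot_row(self):
        res = s.temporal_sparseness(np.array([[1.0, 0, 0, 0]]))
        assert res.values[0] == pytest.approx(0.75, abs=1e-12)  # 1 - 1/M

    def test_constant_row_is_zero(self):
        res = s.temporal_sparseness(np.full((1, 10), 3.0))
        assert res.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_exponential_sparser_than_uniform(self):
        expo = 8.0 * 0.5 ** np.arange(8)
        unif = np.full(8, expo.mean())
        r = s.temporal_sparseness(np.stack([expo, unif]))
        assert r.values[0] > r.values[1]

    def test_population_equals_temporal_of_transpose(self):
        rng = np.random.default_rng(0)
        rates = rng.random((12, 7)) * 5
        pop = s.population_sparseness(rates)
        tmp = s.temporal_sparseness(rates.T)
        np.testing.assert_allclose(pop.values, tmp.values, atol=1e-14)
        assert pop.axis == "population"

    def test_single_active_neuron_per_image(self):
        rates = np.eye(6) * 4.0
        res = s.population_sparseness(rates)
        np.testing.assert_allclose(res.values, 1 - 1 / 6, atol=1e-12)

    def test_zero_rows_flagged_and_excluded(self):
        rates = np.array([[0.0, 0, 0], [1.0, 2, 3]])
        res = s.temporal_sparseness(rates)
        assert np.isnan(res.values[0]) and res.n_excluded == 1
        assert np.isfinite(res.mean)

    def test_negative_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            s.temporal_sparseness(np.array([[-1.0, 2.0]]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 50), min_size=2, max_size=12))
    def test_bounded_in_unit_interval(self, row):
        res = s.temporal_sparseness(np.asarray([row]))
        v = res.values[0]
        assert np.isnan(v) or (-1e-12 <= v <= 1.0)


class TestSortedTuningCurves:
    def test_single_neuron_returns_own_sorted_curve(self):
        rates = np.array([[3.0, 1.0, 2.0]])
        out = s.sorted_tuning_curves(rates)
        np.testing.assert_array_equal(out["curve"], [1.0, 2.0, 3.0])

    def test_curve_is_nondecreasing(self):
        rng = np.random.default_rng(1)
        out = s.sorted_tuning_curves(rng.random((30, 50)))
        assert np.all(np.diff(out["curve"]) >= 0)
        assert out["position"][0] == 0 and out["position"][-1] == 1

    def test_exchangeable_rows_sorting_commutes_with_average(self):
        rng = np.random.default_rng(2)
        rates = rng.exponential(1.0, size=(2000, 40))
        mean_of_sorted = s.sorted_tuning_curves(rates)["curve"]
        sorted_of_mean = np.sort(rates, axis=1).mean(axis=0)
        np.testing.assert_allclose(mean_of_sorted, sorted_of_mean, atol=1e-12)
        # i.i.d. rows: averaged sorted curve close to population quantiles
        quant = np.quantile(rates, (np.arange(40) + 0.5) / 40)
        assert np.abs(mean_of_sorted - quant).max() < 0.25


# -- correlations -------------------------------------------------------------

class TestRateCorrelation:
    def test_duplicated_neuron_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        x = rng.random(20)
        res = s.rate_correlation_matrix(np.stack([x, x, rng.random(20)]))
        assert res.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_pair(self):
        x = np.array([1.0, 2, 3, 4])
        res = s.rate_correlation_matrix(np.stack([x, 5 - x]))
        assert res.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_neurons_mean_near_zero(self):
        rng = np.random.default_rng(4)
        rates = rng.poisson(5.0, size=(20, 1000)).astype(float)
        res = s.rate_correlation_matrix(rates)
        assert abs(res.mean_offdiag) < 0.05

    def test_constant_neurons_excluded(self):
        rates = np.vstack([np.full(10, 2.0),
                           np.random.default_rng(0).random(10)])
        res = s.rate_correlation_matrix(rates)
        assert not res.valid[0] and res.valid[1]
        assert np.isnan(res.matrix[0, 1])

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(5)
        res = s.rate_correlation_matrix(rng.random((8, 30)))
        np.testing.assert_allclose(res.matrix, res.matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(res.matrix), 1.0, atol=1e-12)

    def test_single_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            s.rate_correlation_matrix(np.ones((3, 1)))


class TestRfCorrelation:
    def test_self_and_negation(self):
        g = synth_gabor()
        c = s.rf_correlation_matrix(np.stack([g, -g]), np.stack([g]))
        assert c[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert c[1, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_quadrature_pair_uncorrelated(self):
        a = synth_gabor(phase=0.0)
        b = synth_gabor(phase=np.pi / 2)
        a -= a.mean()
        b -= b.mean()
        c = s.rf_correlation_matrix(a, b)
        assert abs(c[0, 0]) < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DegenerateInputError):
            s.rf_correlation_matrix(np.zeros((2, 8, 8)), np.zeros((2, 9, 9)))


class TestWeightVsRfCorrelation:
    def test_constant_weights_flat_profile(self):
        rng = np.random.default_rng(6)
        corr = rng.uniform(-1, 1, size=(20, 30))
        prof = s.weight_vs_rf_correlation(np.full((20, 30), 2.0), corr)
        filled = prof.bin_means[np.isfinite(prof.bin_means)]
        np.testing.assert_allclose(filled, 2.0, atol=1e-12)

    def test_constructed_monotone_trend_recovered(self):
        rng = np.random.default_rng(7)
        corr = rng.uniform(-1, 1, size=(50, 80))
        w = np.maximum(corr, 0.0)
        prof = s.weight_vs_rf_correlation(w, corr)
        centers = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        ok = np.isfinite(prof.bin_means)
        np.testing.assert_allclose(prof.bin_means[ok],
                                   np.maximum(centers[ok], 0.0), atol=0.011)

    def test_empty_bins_have_zero_count_and_nan_mean(self):
        prof = s.weight_vs_rf_correlation(np.ones((1, 1)),
                                          np.array([[0.5]]))
        assert prof.bin_counts.sum() == 1
        empty = prof.bin_counts == 0
        assert np.all(np.isnan(prof.bin_means[empty]))


# -- Gabor fitting ------------------------------------------------------------

class TestGaborFit:
    def test_exact_gabor_recovered(self):
        rf = synth_gabor(sigma_x=2.0, sigma_y=3.0, fs=0.15)
        fit = s.fit_gabor(rf)
        assert fit.fit_error < 0.01
        assert fit.n_x == pytest.approx(0.30, rel=0.10)
        assert fit.n_y == pytest.approx(0.45, rel=0.10)

    def test_noisy_grid_recovery(self):
        """n_x, n_y recovered within 10% with noise SD = 10% of peak."""
        rng = np.random.default_rng(8)
        for k in range(20):
            # envelopes of >= 2 px keep the map's signal energy well above
            # the injected noise floor, so 10% recovery is identifiable
            sx = rng.uniform(2.0, 3.5)
            sy = rng.uniform(2.0, 3.5)
            fs = rng.uniform(0.12, 0.22)
            rf = synth_gabor(sigma_x=sx, sigma_y=sy, fs=fs,
                             ori=rng.uniform(0, np.pi),
                             phase=rng.uniform(0, 2 * np.pi),
                             x0=8 + rng.uniform(-1, 1),
                             y0=8 + rng.uniform(-1, 1))
            noisy = rf + 0.1 * np.abs(rf).max() * rng.standard_normal(rf.shape)
            fit = s.fit_gabor(noisy)
            assert fit.n_x == pytest.approx(sx * fs, rel=0.10), f"case {k}"
            assert fit.n_y == pytest.approx(sy * fs, rel=0.10), f"case {k}"

    def test_white_noise_map_poorly_fit(self):
        rng = np.random.default_rng(9)
        fit = s.fit_gabor(rng.standard_normal((16, 16)))
        assert fit.fit_error > 0.5

    def test_scale_equivariance(self):
        rf = synth_gabor(sigma_x=2.5, sigma_y=2.0, fs=0.18)
        a = s.fit_gabor(rf)
        b = s.fit_gabor(5.0 * rf)
        assert b.fit_error == pytest.approx(a.fit_error, rel=1e-3, abs=1e-9)
        assert b.n_x == pytest.approx(a.n_x, rel=1e-3)
        assert b.n_y == pytest.approx(a.n_y, rel=1e-3)

    def test_flat_map_flagged_failed(self):
        fit = s.fit_gabor(np.full((16, 16), 0.7))
        assert fit.failed and not fit.well_fit


# -- STA ----------------------------------------------------------------------

class TestSta:
    def test_linear_poisson_probe_recovers_planted_filter(self):
        """STA of a rectified-linear Poisson probe matches its filter."""
        rng = np.random.default_rng(10)
        g = synth_gabor(p=16)
        g /= np.linalg.norm(g)
        n_w = 20_000
        noise = rng.standard_normal((n_w, 16, 16))
        drive = np.einsum("kij,ij->k", noise, g)
        rates = np.maximum(drive, 0.0)
        sta = np.einsum("k,kij->ij", rates, noise) / rates.sum()
        cos = np.sum(sta * g) / np.linalg.norm(sta)
        assert cos > 0.9

    def test_rate_scaling_leaves_sta_unchanged(self):
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((500, 8, 8))
        rates = rng.random(500)
        f1 = np.einsum("k,kij->ij", rates, noise) / rates.sum()
        f2 = np.einsum("k,kij->ij", 2 * rates, noise) / (2 * rates).sum()
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_rf_mosaic_renders(self, tmp_path):
        from sparsev1.analysis import ReceptiveFieldSet, plot_rf_mosaic
        maps = np.stack([synth_gabor(p=8, sigma_x=1.5, sigma_y=2.0, fs=0.2)
                         for _ in range(4)])
        rfs = ReceptiveFieldSet(maps=maps, responsive=np.ones(4, bool),
                                population="E", n_stimuli=1)
        out = tmp_path / "mosaic.png"
        plot_rf_mosaic(rfs, out)
        assert out.stat().st_size > 0

    def test_network_sta_shapes_and_flags(self, tiny_trainer):
        rfs = s.estimate_sta(tiny_trainer, 60, seed=1, duration_ms=200.0)
        assert rfs.maps.shape == (16, 8, 8)
        assert np.all(np.isfinite(rfs.maps))
        silent = ~rfs.responsive
        assert np.all(rfs.maps[silent] == 0)


# -- balance ------------------------------------------------------------------

class TestTightBalanceXcorr:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(12)
        x = rng.random(600)  # positive trace: |.| convention is a no-op
        c = s.tight_balance_xcorr(x, x, exclude_initial_ms=100, max_lag_ms=50)
        assert c.peak_lag_ms == 0.0
        assert c.peak_value == pytest.approx(1.0, abs=1e-12)

    def test_shifted_copy_peaks_at_shift(self):
        rng = np.random.default_rng(13)
        x = rng.random(1000)
        y = np.roll(x, 3)  # y lags x by 3 steps
        c = s.tight_balance_xcorr(x, y, exclude_initial_ms=100, max_lag_ms=20)
        assert c.peak_lag_ms == 3.0

    def test_independent_noise_small_peak(self):
        rng = np.random.default_rng(14)
        c = s.tight_balance_xcorr(rng.standard_normal(10_100),
                                  rng.standard_normal(10_100),
                                  exclude_initial_ms=100, max_lag_ms=50)
        assert abs(c.peak_value) < 0.1

    def test_short_trace_rejected(self):
        with pytest.raises(DegenerateInputError):
            s.tight_balance_xcorr(np.ones(150), np.ones(150),
                                  exclude_initial_ms=100, max_lag_ms=50)


class TestLooseBalance:
    def test_probe_selection_and_summary(self, tiny_trainer):
        rfs = s.estimate_sta(tiny_trainer, 80, seed=2, duration_ms=200.0)
        res = probe_loose_balance(tiny_trainer, tiny_trainer.pool, rfs,
                                  n_neurons=4, seed=0, duration_ms=300.0)
        assert res.mean_exc.shape == (3, len(res.neurons))
        assert res.categories == BALANCE_CATEGORIES
        # excitatory drive ranks with the patch/RF correlation on average
        assert res.mean_exc[2].mean() >= res.mean_exc[0].mean()
        # inhibition-only voltages are non-positive
        assert np.all(res.mean_inh <= 1e-9)

    def test_selection_deterministic(self, tiny_trainer):
        rfs = s.estimate_sta(tiny_trainer, 80, seed=2, duration_ms=200.0)
        a = probe_loose_balance(tiny_trainer, tiny_trainer.pool, rfs,
                                n_neurons=3, seed=5, duration_ms=200.0)
        b = probe_loose_balance(tiny_trainer, tiny_trainer.pool, rfs,
                                n_neurons=3, seed=5, duration_ms=200.0)
        np.testing.assert_array_equal(a.patch_index, b.patch_index)
        np.testing.assert_allclose(a.mean_full, b.mean_full, atol=1e-12)

    def test_small_pool_rejected(self, tiny_trainer):
        rfs = s.estimate_sta(tiny_trainer, 30, seed=2, duration_ms=200.0)
        tiny_pool = s.StimulusBatch(
            patches=tiny_trainer.pool.patches[:2],
            on_rates=tiny_trainer.pool.on_rates[:2],
            off_rates=tiny_trainer.pool.off_rates[:2])
        with pytest.raises(DegenerateInputError):
            probe_loose_balance(tiny_trainer, tiny_pool, rfs, n_neurons=2)

    def test_probe_linearity_through_analysis_layer(self, tiny_trainer):
        """Total trace equals excitation + inhibition traces at sigma_xi=0."""
        import dataclasses
        quiet = dataclasses.replace(tiny_trainer.params, sigma_xi=0.0)
        saved = tiny_trainer.params
        tiny_trainer.params = quiet
        try:
            tr = s.probe_neuron(tiny_trainer, tiny_trainer.pool.rates[0],
                                neuron=0, duration_ms=300.0, seed=3)
        finally:
            tiny_trainer.params = saved
        np.testing.assert_allclose(
            tr.full, tr.excitation_only + tr.inhibition_only, atol=1e-9)
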