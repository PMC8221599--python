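import numpy as np
import pytest
from scipy.stats import pearsonr

from ptcmap.hrf_model import CANONICAL_HRF, convolve_prediction, double_gamma_kernel
from ptcmap.stimulus_design import ApertureMatrix
from ptcmap.tuning_fit import (
    MU_GRID_DEFAULT,
    SIGMA_GRID_DEFAULT,
    FitResult,
    GaussianPTC,
    MoGPTC,
    bic,
    bic_compare,
    coarse_fit,
    coarse_fit_batch,
    fine_fit,
    fit_mog,
    neural_response,
    neural_time_course,
    prediction_grid,
    two_pass_fit,
)

from conftest import MU_SMALL, SIGMA_SMALL


def synth_series(mu, sigma, aperture, hrf=CANONICAL_HRF, tr=1.0):
    # noiseless observed series: forward model plus the preprocessing
    # band-pass that real data receive
    from ptcmap.preprocessing import dct_filter

    neural = neural_time_course(mu, sigma, aperture)[0]
    bold = convolve_prediction(neural, double_gamma_kernel(hrf, tr), tr)
    return dct_filter(bold, tr)


class TestDomainTypes:
    def test_gaussian_sigma_positive(self):
        with pytest.raises(ValueError):
            GaussianPTC(mu=0.5, sigma=0.0)

    def test_mog_invariants(self):
        with pytest.raises(ValueError):
            MoGPTC(0.7, 0.3, 0.1, 0.1, 1.0, 1.0)  # eye below mouth
        with pytest.raises(ValueError):
            MoGPTC(0.3, 0.7, 0.1, 0.1, -1.0, 1.0)  # negative amplitude


class TestNeuralResponse:
    def test_zero_aperture(self):
        x = np.linspace(0, 1, 50)
        ptc = GaussianPTC(0.5, 0.1)
        assert neural_response(ptc, np.zeros(50), x) == 0.0

    def test_symmetry_about_center(self, spatial_aperture):
        x = spatial_aperture.bin_centers
        row = np.exp(-((x - 0.5) ** 2) / 0.02)  # symmetric aperture row
        d = 0.17
        a = neural_response(GaussianPTC(0.5 - d, 0.1), row, x)
        b = neural_response(GaussianPTC(0.5 + d, 0.1), row, x)
        assert a == pytest.approx(b, rel=1e-10)

    def test_matches_quadrature_oracle(self):
        # indicator of [0.4, 0.5], mu=0.45, sigma=0.05 vs dense integration
        from scipy.integrate import quad

        n_bins = 2000
        edges = np.linspace(0, 1, n_bins + 1)
        x = 0.5 * (edges[:-1] + edges[1:])
        row = ((x >= 0.4) & (x < 0.5)).astype(float)
        ptc = GaussianPTC(0.45, 0.05)
        got = neural_response(ptc, row, x)
        oracle = quad(lambda u: np.exp(-((u - 0.45) ** 2) / (2 * 0.05**2)), 0.4, 0.5)[0]
        assert got == pytest.approx(oracle, rel=0.01)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            neural_response(GaussianPTC(0.5, 0.1), np.zeros(10), np.linspace(0, 1, 11))


class TestPredictionGrid:
    def test_default_grid_sizes(self):
        assert MU_GRID_DEFAULT.size == 281
        assert SIGMA_GRID_DEFAULT.size == 133

    def test_default_grid_ranges(self):
        assert MU_GRID_DEFAULT[0] == pytest.approx(-0.2)
        assert MU_GRID_DEFAULT[-1] == pytest.approx(1.2)
        assert SIGMA_GRID_DEFAULT[0] == pytest.approx(2.0**-5.6)
        assert SIGMA_GRID_DEFAULT[-1] == pytest.approx(2.0)

    def test_retained_predictions_standardized(self, small_grid):
        preds = small_grid.predictions[small_grid.valid]
        np.testing.assert_allclose(preds.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(preds.std(axis=1), 1, atol=1e-10)

    def test_degenerate_predictions_flagged(self, spatial_aperture):
        # far-outside mu with tiny sigma yields a flat neural response
        grid = prediction_grid(spatial_aperture, np.array([-0.2]), np.array([0.01]))
        assert not grid.valid.any()

    def test_empty_grid_raises(self, spatial_aperture):
        with pytest.raises(ValueError, match="empty"):
            prediction_grid(spatial_aperture, np.array([]), np.array([0.1]))

    def test_row_order_mu_major(self, small_grid):
        n_sig = SIGMA_SMALL.size
        assert np.all(small_grid.mu[:n_sig] == small_grid.mu[0])
        np.testing.assert_allclose(small_grid.sigma[:n_sig], SIGMA_SMALL)


def brute_force_fit(series, aperture, mu_grid, sigma_grid, hrf=CANONICAL_HRF):
    """Independent oracle: explicit loop over all grid pairs via scipy.pearsonr."""
    from ptcmap.preprocessing import dct_filter

    kernel = double_gamma_kernel(hrf, 1.0)
    x = aperture.bin_centers
    dx = x[1] - x[0]
    best = (-1.0, None, None)
    for mu in mu_grid:
        for sigma in sigma_grid:
            g = np.exp(-((x - mu) ** 2) / (2 * sigma**2))
            neural = aperture.weights @ g * dx
            pred = dct_filter(np.convolve(neural, kernel)[: len(neural)], 1.0)
            if np.std(pred) < 1e-10:
                continue
            r = pearsonr(pred, series)[0]
            if r**2 > best[0] + 1e-12:
                best = (r**2, mu, sigma)
    return best


class TestCoarseFit:
    def test_noiseless_grid_point_recovered(self, small_grid, spatial_aperture):
        series = synth_series(0.5, 0.25, spatial_aperture)
        grid = prediction_grid(spatial_aperture, np.array([0.3, 0.5, 0.7]),
                               np.array([0.1, 0.25, 0.5]))
        fit = coarse_fit(series, grid)
        assert fit.params.mu == 0.5
        assert fit.params.sigma == 0.25
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_off_grid_mu_within_one_step(self, spatial_aperture, full_grid):
        series = synth_series(0.5012, 0.25, spatial_aperture)
        fit = coarse_fit(series, full_grid)
        assert abs(fit.params.mu - 0.5012) <= 0.005

    def test_equals_brute_force_oracle(self, spatial_aperture, small_grid, rng):
        for _ in range(50):
            series = rng.standard_normal(192)
            fit = coarse_fit(series, small_grid)
            r2_o, mu_o, sig_o = brute_force_fit(series, spatial_aperture,
                                                MU_SMALL, SIGMA_SMALL)
            assert fit.r2 == pytest.approx(r2_o, abs=1e-9)
            assert fit.params.mu == pytest.approx(mu_o, abs=1e-12)
            assert fit.params.sigma == pytest.approx(sig_o, rel=1e-12)

    def test_constant_series_invalid(self, small_grid):
        fit = coarse_fit(np.ones(192), small_grid)
        assert not fit.valid
        assert fit.r2 == 0.0

    def test_white_noise_r2_below_threshold(self, small_grid, rng):
        series = rng.standard_normal((192, 300))
        r2 = np.array([f.r2 for f in coarse_fit_batch(series, small_grid)])
        assert np.median(r2) < 0.3

    def test_r2_invariant_to_affine_transform(self, spatial_aperture, small_grid, rng):
        series = rng.standard_normal(192)
        f1 = coarse_fit(series, small_grid)
        f2 = coarse_fit(3.5 * series - 2.0, small_grid)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)
        assert f1.params.mu == f2.params.mu

    def test_beta_scales_with_amplitude(self, spatial_aperture, small_grid):
        series = synth_series(0.5, 0.25, spatial_aperture)
        f1 = coarse_fit(series, small_grid)
        f2 = coarse_fit(2.0 * series, small_grid)
        assert f2.params.beta == pytest.approx(2.0 * f1.params.beta, rel=1e-9)

    def test_length_mismatch_raises(self, small_grid):
        with pytest.raises(ValueError, match="length"):
            coarse_fit(np.zeros(100), small_grid)


class TestFineFit:
    def test_noiseless_off_grid_recovery(self, spatial_aperture, full_grid):
        # oracle check at dense grid resolution: fine fit should land within
        # 0.001 of the generative off-grid mu
        series = synth_series(0.5012, 0.25, spatial_aperture)
        init = coarse_fit(series, full_grid)
        refined = fine_fit(series, init, spatial_aperture)
        assert abs(refined.params.mu - 0.5012) <= 0.001
        assert refined.r2 >= init.r2

    def test_init_at_optimum_unchanged(self, spatial_aperture, full_grid):
        series = synth_series(0.5, 0.25, spatial_aperture)
        init = coarse_fit(series, full_grid)
        refined = fine_fit(series, init, spatial_aperture)
        assert abs(refined.params.mu - init.params.mu) < 1e-3
        assert refined.r2 >= init.r2 - 1e-12

    def test_never_decreases_r2_on_noise(self, spatial_aperture, small_grid, rng):
        for _ in range(25):
            series = rng.standard_normal(192)
            init = coarse_fit(series, small_grid)
            refined = fine_fit(series, init, spatial_aperture)
            assert refined.r2 >= init.r2 - 1e-12


class TestTwoPassFit:
    def _cohort(self, hrf, seed, n=80, noise_sd=5.0):
        from ptcmap.synthetic_data import make_ground_truth, simulate_dataset
        from ptcmap.stimulus_design import make_run_design

        design = make_run_design("spatial")
        truth = make_ground_truth(n_vertices=n, n_hemispheres=4, seed=seed,
                                  noise_sd=noise_sd, hrf=hrf)
        data = simulate_dataset(truth, {"spatial": design})
        return data["spatial"].values, truth

    def test_delayed_hrf_improves_pass2(self, spatial_aperture):
        from ptcmap.hrf_model import HRFParams

        series, _ = self._cohort(HRFParams(peak_delay=7.5), seed=21)
        res = two_pass_fit(series, spatial_aperture,
                           mu_grid=MU_SMALL, sigma_grid=SIGMA_SMALL)
        p1 = np.median([f.r2 for f in res.pass1])
        p2 = np.median([f.r2 for f in res.pass2])
        assert p2 >= p1

    def test_canonical_cohort_stable_mu(self, spatial_aperture):
        series, _ = self._cohort(CANONICAL_HRF, seed=22)
        res = two_pass_fit(series, spatial_aperture,
                           mu_grid=MU_SMALL, sigma_grid=SIGMA_SMALL)
        mu1 = np.array([f.params.mu for f in res.pass1])
        mu2 = np.array([f.params.mu for f in res.pass2])
        step = MU_SMALL[1] - MU_SMALL[0]
        assert np.mean(np.abs(mu1 - mu2) <= step + 1e-12) >= 0.95

    def test_no_inclusion_falls_back_to_canonical(self, spatial_aperture, rng):
        series = rng.standard_normal((192, 10))
        with pytest.warns(RuntimeWarning, match="canonical"):
            res = two_pass_fit(series, spatial_aperture,
                               mu_grid=MU_SMALL, sigma_grid=SIGMA_SMALL,
                               hrf_inclusion_r2=0.99)
        assert res.hrf_is_canonical

    def test_supplied_hrf_skips_estimation(self, spatial_aperture):
        from ptcmap.hrf_model import HRFParams

        series, _ = self._cohort(CANONICAL_HRF, seed=23, n=40)
        slow = HRFParams(peak_delay=7.0)
        res = two_pass_fit(series, spatial_aperture, fitted_hrf=slow,
                           mu_grid=MU_SMALL, sigma_grid=SIGMA_SMALL)
        assert res.hrf == slow


class TestMoG:
    def test_free_parameter_count(self):
        from ptcmap.tuning_fit import N_FREE_MOG, N_FREE_SIMPLE

        assert N_FREE_SIMPLE == 3
        assert N_FREE_MOG == 4

    def test_single_gaussian_at_eye_suppresses_mouth(self, face_aperture):
        series = synth_series(0.365, 0.08, face_aperture)
        fit = fit_mog(series, face_aperture)
        assert fit.params.beta_mouth / fit.params.beta_eye < 0.1

    def test_bimodal_series_prefers_mog(self, face_aperture):
        x = face_aperture.bin_centers
        dx = face_aperture.bin_width
        bimodal = (np.exp(-((x - 0.365) ** 2) / (2 * 0.05**2))
                   + np.exp(-((x - 0.635) ** 2) / (2 * 0.05**2)))
        neural = face_aperture.weights @ bimodal * dx
        kernel = double_gamma_kernel(CANONICAL_HRF, 1.0)
        from ptcmap.preprocessing import dct_filter

        series = dct_filter(convolve_prediction(neural, kernel, 1.0), 1.0)
        mog = fit_mog(series, face_aperture)
        simple = coarse_fit(series, prediction_grid(face_aperture, MU_SMALL, SIGMA_SMALL))
        assert mog.r2 > simple.r2

    def test_constant_series_invalid(self, face_aperture):
        fit = fit_mog(np.ones(192), face_aperture)
        assert not fit.valid


class TestBIC:
    def test_closed_form(self):
        assert bic(100.0, 100, 3) == pytest.approx(3 * np.log(100), abs=1e-12)

    def test_equal_rss_delta_is_log_n(self):
        n = 192
        assert bic(5.0, n, 4) - bic(5.0, n, 3) == pytest.approx(np.log(n), abs=1e-12)
        assert np.log(192) == pytest.approx(5.257, abs=0.001)

    def test_perfect_fit_sentinel(self):
        assert bic(0.0, 100, 3) == -np.inf

    def test_simple_cohort_prefers_simple(self, face_aperture, rng):
        # simple-Gaussian-generated vertices: median dBIC (MoG - simple) > 0
        grid = prediction_grid(face_aperture, MU_SMALL, SIGMA_SMALL)
        n_v = 40
        series = np.empty((192, n_v))
        for v in range(n_v):
            clean = synth_series(rng.uniform(0.25, 0.75), rng.uniform(0.05, 0.4),
                                 face_aperture)
            clean = (clean - clean.mean()) / clean.std()
            series[:, v] = clean + 1.2 * rng.standard_normal(192)
        fits_simple = coarse_fit_batch(series, grid)
        fits_mog = [fit_mog(series[:, v], face_aperture) for v in range(n_v)]
        cmp = bic_compare(fits_simple, fits_mog, series, face_aperture)
        assert cmp.median_delta > 0
        assert cmp.delta_bic.size == n_v

    def test_mismatched_inputs_raise(self, face_aperture):
        with pytest.raises(ValueError, match="paired"):
            bic_compare([], [FitResult(params=GaussianPTC(0.5, 0.1), r2=0.5)],
                        np.zeros((10, 1)), face_aperture)
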