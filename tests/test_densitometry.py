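"""Densitometry pipeline: filtering, fitting, AUC, SNR, and QC behavior."""

import math

import numpy as np
import pytest

from cytoblot import densitometry, synthetic
from cytoblot.densitometry import (
    IntensityProfile,
    PeakFit,
    TWO_SIGMA_FRACTION,
    compute_auc,
    compute_snr,
    fit_gaussian,
    remove_outliers,
)
from cytoblot.synthetic import PopulationSpec, RenderSpec


def gaussian_profile(A=1000.0, mu=350.0, sigma=66.0, b=0.0, L=700.0, px=10.0):
    x = np.arange(px / 2, L, px)
    return IntensityProfile(distance=x, value=A * np.exp(-((x - mu) ** 2) / (2 * sigma**2)) + b,
                            baseline=0.0)


class TestRemoveOutliers:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 37.0)
        np.testing.assert_array_equal(remove_outliers(img), img)

    def test_single_hot_pixel_replaced_neighbors_kept(self):
        img = np.full((21, 21), 100.0)
        img[10, 10] += 1000.0
        out = remove_outliers(img, radius=2, threshold=50.0)
        assert out[10, 10] == 100.0
        mask = np.ones_like(img, bool)
        mask[10, 10] = False
        np.testing.assert_array_equal(out[mask], img[mask])

    def test_smooth_band_within_threshold_unchanged(self):
        # per-window gradient below the threshold: the filter must not touch it
        x = np.arange(100)
        band = 500.0 * np.exp(-((x - 50.0) ** 2) / (2 * 20.0**2))
        img = np.tile(band, (9, 1))
        out = remove_outliers(img, radius=2, threshold=50.0)
        np.testing.assert_array_equal(out, img)

    def test_idempotent_on_hot_pixel_regime(self, rng):
        # scanner noise well below the threshold plus sparse hot pixels: the
        # single-pass replacement is a fixed point
        img = rng.normal(100, 5, size=(30, 30))
        img[5, 5] = 5000.0
        img[20, 11] = 900.0
        once = remove_outliers(img)
        twice = remove_outliers(once)
        np.testing.assert_array_equal(once, twice)

    def test_dark_outlier_kept_unless_two_sided(self):
        img = np.full((11, 11), 500.0)
        img[5, 5] = 0.0
        assert remove_outliers(img)[5, 5] == 0.0
        assert remove_outliers(img, two_sided=True)[5, 5] == 500.0


class TestFitGaussian:
    def test_noiseless_recovery_to_machine_precision(self):
        fit = fit_gaussian(gaussian_profile(A=1000, mu=350, sigma=66))
        assert fit.qc_pass
        assert fit.amplitude == pytest.approx(1000, rel=1e-6)
        assert fit.center == pytest.approx(350, rel=1e-6)
        assert fit.sigma == pytest.approx(66, rel=1e-6)

    def test_flat_noise_lane_fails_r2_gate(self, rng):
        x = np.arange(5, 700, 10.0)
        prof = IntensityProfile(distance=x, value=rng.normal(0, 5, len(x)), baseline=0.0)
        fit = fit_gaussian(prof)
        assert fit.r_squared <= 0.7
        assert fit.reason == "low_r2"

    def test_equal_bimodal_fails_single_gaussian_fit(self):
        x = np.arange(5, 700, 10.0)
        y = 500 * np.exp(-((x - 250) ** 2) / (2 * 30**2)) + 500 * np.exp(
            -((x - 450) ** 2) / (2 * 30**2)
        )
        fit = fit_gaussian(IntensityProfile(distance=x, value=y, baseline=0.0))
        assert fit.r_squared < 0.7
        assert not fit.qc_pass

    def test_monotone_smear_rejected_as_unresolved(self):
        x = np.arange(5, 700, 10.0)
        y = 90.0 * np.exp(-x / 100.0)
        fit = fit_gaussian(IntensityProfile(distance=x, value=y, baseline=0.0))
        assert not fit.qc_pass
        assert fit.reason in ("unresolved", "low_r2")

    def test_nonfinite_profile_raises(self):
        prof = gaussian_profile()
        prof.value[3] = np.nan
        with pytest.raises(ValueError):
            fit_gaussian(prof)

    def test_short_profile_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian(IntensityProfile(distance=np.arange(5.0), value=np.ones(5), baseline=0.0))


class TestAucAndSnr:
    def test_two_sigma_window_closed_form(self):
        # integral over ±2σ of A·exp(...) = A σ √(2π) erf(√2)
        A, sigma = 1000.0, 66.0
        prof = gaussian_profile(A=A, sigma=sigma, px=1.0)
        fit = fit_gaussian(prof)
        auc = compute_auc(fit, prof)
        expected = A * sigma * math.sqrt(2 * math.pi) * TWO_SIGMA_FRACTION
        assert auc == pytest.approx(expected, rel=1e-3)
        assert not fit.truncated_window

    def test_zero_amplitude_zero_auc(self):
        prof = gaussian_profile(A=0.0)
        fit = PeakFit(amplitude=0.0, center=350.0, sigma=66.0, baseline=0.0,
                      r_squared=1.0, reason="pass", qc_pass=True)
        assert compute_auc(fit, prof) == 0.0

    def test_truncated_window_flagged(self):
        prof = gaussian_profile(mu=650.0, sigma=66.0)
        fit = PeakFit(amplitude=1000.0, center=650.0, sigma=66.0, baseline=0.0,
                      r_squared=1.0, reason="pass", qc_pass=True)
        compute_auc(fit, prof)
        assert fit.truncated_window

    def test_snr_boundary_is_strict(self, rng):
        bg = rng.normal(0, 100, size=400)
        sd = np.std(bg, ddof=1)
        fit = PeakFit(amplitude=3.0 * sd, center=350, sigma=66, baseline=0,
                      r_squared=0.99, reason="pass", qc_pass=True)
        snr = compute_snr(fit, bg)
        assert snr == pytest.approx(3.0)
        assert fit.reason == "low_snr" and not fit.qc_pass

    def test_zero_background_variance_gives_infinite_snr(self):
        fit = PeakFit(amplitude=10.0, center=350, sigma=66, baseline=0,
                      r_squared=0.99, reason="pass", qc_pass=True)
        assert compute_snr(fit, np.zeros(50)) == np.inf
        assert fit.qc_pass

    def test_empty_background_raises(self):
        fit = PeakFit(amplitude=10.0, reason="pass", qc_pass=True)
        with pytest.raises(ValueError):
            compute_snr(fit, np.array([]))


class TestQuantifyArray:
    def test_noiseless_oracle_equivalence(self, noiseless_render):
        image, truth = noiseless_render
        blots, report = densitometry.quantify_array(image, outlier_filter=False)
        assert report.n_pass == report.n_lanes
        m = blots.merge(truth, on=["lane_id", "side"])
        rel = np.abs(m.auc / TWO_SIGMA_FRACTION - m.true_auc) / m.true_auc
        assert rel.max() < 0.005

    def test_recovered_centers_match_migration_distance(self, noiseless_render):
        # bands drawn at 350 ± 16 μm: fitted centers must average within that
        image, truth = noiseless_render
        blots, _ = densitometry.quantify_array(image, outlier_filter=False)
        assert blots.center_um.mean() == pytest.approx(350.0, abs=16.0)

    def test_snr_tracks_generator_noise(self, small_population):
        # amplitude / noise_sd should be recovered within sampling error
        spec = RenderSpec(noise_sd=10.0, grid=(10, 6))
        cells = small_population.copy()
        sigma = spec.peak_width_mean
        target_amp = 100.0
        for col in ("F", "G"):
            cells[col] = target_amp * sigma * np.sqrt(2 * np.pi)
        image, _ = synthetic.render_array(cells, spec, seed=33)
        blots, _ = densitometry.quantify_array(image, outlier_filter=False)
        ok = blots[blots.qc]
        assert len(ok) > 50
        assert np.median(ok.snr) == pytest.approx(10.0, rel=0.3)

    def test_dispersed_lanes_never_pass(self, small_population):
        spec = RenderSpec(noise_sd=5.0, grid=(10, 6), dispersed_fraction=1.0)
        image, _ = synthetic.render_array(small_population, spec, seed=13)
        _, report = densitometry.quantify_array(image)
        assert report.n_pass == 0

    def test_qc_rejection_rate_at_least_dispersed_fraction(self, small_population):
        spec = RenderSpec(noise_sd=2.0, grid=(10, 6), dispersed_fraction=0.3)
        image, truth = synthetic.render_array(small_population, spec, seed=14)
        blots, report = densitometry.quantify_array(image)
        m = blots.merge(truth, on=["lane_id", "side"])
        assert (~m[m.lane_class == "dispersed"].qc).all()
        assert (report.n_lanes - report.n_pass) / report.n_lanes >= 0.3

    def test_monotonicity_in_true_auc(self):
        # same lane geometry, doubled abundance -> recovered AUC increases
        base = synthetic.sample_population(PopulationSpec(n_cells=1, seed=2))
        spec = RenderSpec(noise_sd=0.0, grid=(1, 1))
        aucs = []
        for scale in (1.0, 2.0, 4.0):
            cells = base.copy()
            cells[["F", "G"]] *= scale
            image, _ = synthetic.render_array(cells, spec, seed=5)
            blots, _ = densitometry.quantify_array(image, outlier_filter=False)
            aucs.append(blots[blots.side == "complex"].auc.iloc[0])
        assert aucs[0] < aucs[1] < aucs[2]

    def test_manual_reject_list(self, noiseless_render):
        image, _ = noiseless_render
        blots, _ = densitometry.quantify_array(
            image, outlier_filter=False, manual_reject={(0, "monomer")}
        )
        row = blots[(blots.lane_id == 0) & (blots.side == "monomer")].iloc[0]
        assert row.reason == "manual_reject" and not row.qc

    def test_cell_table_assembly(self, noiseless_render):
        image, truth = noiseless_render
        blots, _ = densitometry.quantify_array(image, outlier_filter=False)
        table = densitometry.blots_to_cell_table(blots, truth)
        assert {"F", "G", "f_ratio", "cell_id"}.issubset(table.columns)
        assert table.f_ratio.between(0, 1).all()
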