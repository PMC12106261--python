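"""Image-quality metrics: CRC, CNR, CV, lung error, CF, RC, FWHM."""

import math

import numpy as np
import pytest

from leadspect.metrics import (
    CalibrationResult,
    VOIStats,
    analyze_iq,
    ball_gaussian_profile,
    calibrate_on_cylinder,
    calibration_factor,
    cnr,
    counts_to_concentration,
    crc,
    cv_bg,
    fwhm_from_sphere,
    lung_error,
    recovery_coefficient,
)
from leadspect.phantoms import PhantomSpec, VoxelGrid, build_cylinder_voi, build_voi_set
from leadspect.simulate import ImagingSystemModel, simulate_spect_volume

from conftest import grid_for


def stats(mean_sphere=100.0, mean_bg=50.0, sd_bg=5.0, mean_bg_large=50.0,
          sd_bg_large=5.0, mean_lung=10.0):
    return VOIStats(mean_sphere, mean_bg, sd_bg, mean_bg_large, sd_bg_large, mean_lung)


class TestContrastMetrics:
    def test_crc_perfect_recovery(self):
        assert crc(stats(mean_sphere=400.0, mean_bg=50.0), true_ratio=8.0) == pytest.approx(100.0)

    def test_crc_published_largest_sphere(self):
        # measured ratio 5.22 at true ratio 7.73 -> printed CRC 62.7
        s = stats(mean_sphere=5.22, mean_bg=1.0)
        assert crc(s, 7.73) == pytest.approx(62.7, abs=0.05)

    def test_crc_no_contrast(self):
        assert crc(stats(mean_sphere=50.0, mean_bg=50.0), 8.0) == 0.0

    def test_crc_invalid_ratio(self):
        with pytest.raises(ValueError):
            crc(stats(), 1.0)

    def test_cnr_arithmetic(self):
        assert cnr(stats(150.0, 100.0, 10.0)) == pytest.approx(5.0)
        assert cnr(stats(mean_sphere=50.0, mean_bg=50.0)) == 0.0

    def test_cnr_degenerate_sigma(self):
        with pytest.raises(ValueError):
            cnr(stats(sd_bg=0.0))


class TestNoiseAndLung:
    def test_cv_constant_background(self):
        assert cv_bg(stats(sd_bg_large=0.0)) == 0.0

    def test_cv_poisson(self, rng):
        vals = rng.poisson(100.0, 200_000).astype(float)
        s = stats(mean_bg_large=vals.mean(), sd_bg_large=vals.std(ddof=1))
        assert cv_bg(s) == pytest.approx(10.0, rel=0.02)

    def test_cv_scale_invariant(self):
        s1 = stats(mean_bg_large=50.0, sd_bg_large=5.0)
        s2 = stats(mean_bg_large=500.0, sd_bg_large=50.0)
        assert cv_bg(s1) == pytest.approx(cv_bg(s2))

    def test_lung_error_cases(self):
        assert lung_error(stats(mean_lung=0.0)) == 0.0
        assert lung_error(stats(mean_lung=50.0, mean_bg_large=50.0)) == pytest.approx(100.0)

    def test_lung_error_monotone_in_penetration(self):
        base = stats(mean_lung=5.0, mean_bg_large=50.0)
        raised = stats(mean_lung=5.0 + 10.0, mean_bg_large=50.0 + 10.0)
        assert lung_error(raised) > lung_error(base)


class TestQuantification:
    def test_cf_arithmetic(self):
        cal = calibration_factor(6000.0, 1000.0, 60.0, 0.001)
        assert cal.cf_cps_per_mbq == pytest.approx(100.0)

    def test_cf_halves_when_time_doubles(self):
        a = calibration_factor(6000.0, 1000.0, 60.0, 0.001).cf_cps_per_mbq
        b = calibration_factor(6000.0, 1000.0, 120.0, 0.001).cf_cps_per_mbq
        assert b == pytest.approx(a / 2.0)

    def test_cf_invalid(self):
        with pytest.raises(ValueError):
            calibration_factor(100.0, 0.0, 60.0, 0.001)

    def test_rc_trivial(self):
        assert recovery_coefficient(0.005, 0.005) == 1.0
        with pytest.raises(ValueError):
            recovery_coefficient(1.0, 0.0)

    def test_cf_matches_simulator_sensitivity(self):
        # eroded VOI on a noiseless unblurred cylinder: CF equals the model sensitivity
        spec = PhantomSpec.uniform_cylinder(17.6)
        grid = grid_for(spec, 2.4)
        model = ImagingSystemModel(sensitivity_cps_per_mbq=124.9, psf_fwhm_mm=0.0)
        ds = simulate_spect_volume(spec, model, grid, 600.0, 0, noise=False)
        voi = build_cylinder_voi(spec, grid)
        cal = calibrate_on_cylinder(ds.images["photopeak"], voi, grid, 600.0, 17.6 / 1000.0)
        assert cal.cf_cps_per_mbq == pytest.approx(124.9, rel=1e-9)


class TestFwhm:
    def test_profile_matches_monte_carlo_oracle(self, rng):
        # fraction of Gaussian-displaced points landing inside the ball
        radius, sigma = 14.0, 5.0
        for r in (0.0, 7.0, 14.0, 20.0):
            pts = np.array([0.0, 0.0, r]) + rng.normal(0.0, sigma, (200_000, 3))
            mc = (np.linalg.norm(pts, axis=1) <= radius).mean()
            assert ball_gaussian_profile(r, radius, sigma) == pytest.approx(mc, abs=5e-3)

    def test_recovers_generator_blur(self, nema_grid):
        sigma = 5.0
        spec = PhantomSpec.nema_iq(40.0, 0.0)
        model = ImagingSystemModel(
            sensitivity_cps_per_mbq=100.0, psf_fwhm_mm=2 * math.sqrt(2 * math.log(2)) * sigma
        )
        ds = simulate_spect_volume(spec, model, nema_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, nema_grid)
        res = fwhm_from_sphere(ds.images["photopeak"], nema_grid, vois.sphere_centers[37.0], 18.5)
        assert res.converged
        assert res.fwhm_mm == pytest.approx(11.774, rel=0.05)

    def test_unblurred_sphere_fwhm_below_grid(self, nema_grid):
        spec = PhantomSpec.nema_iq(40.0, 0.0)
        model = ImagingSystemModel(sensitivity_cps_per_mbq=100.0, psf_fwhm_mm=0.0)
        ds = simulate_spect_volume(spec, model, nema_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, nema_grid)
        res = fwhm_from_sphere(ds.images["photopeak"], nema_grid, vois.sphere_centers[37.0], 18.5)
        assert res.converged
        assert res.fwhm_mm < 1.5 * nema_grid.voxel_size_mm

    def test_flat_profile_flagged_not_faked(self, nema_grid, nema_vois):
        flat = np.full(nema_grid.shape, 3.0)
        res = fwhm_from_sphere(flat, nema_grid, nema_vois.sphere_centers[37.0], 18.5)
        assert not res.converged
        assert res.fwhm_mm is None


class TestAnalyzeIQ:
    @pytest.fixture(scope="class")
    def identity_report(self, nema_grid):
        spec = PhantomSpec.nema_iq(38.4, 4.8)  # exact 8:1
        model = ImagingSystemModel(sensitivity_cps_per_mbq=100.0, psf_fwhm_mm=0.0)
        ds = simulate_spect_volume(spec, model, nema_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, nema_grid)
        cal = CalibrationResult(100.0, 1.0, 1.0, 600.0, 1.0)
        return analyze_iq(ds.images, vois, spec, cal, 600.0, fit_fwhm=False)

    def test_cardinality(self, identity_report):
        assert len(identity_report.crc_pct) == 6
        assert len(identity_report.cnr) == 6
        assert len(identity_report.rc) == 6
        assert identity_report.rc_bg is not None

    def test_identity_metrics_perfect(self, identity_report):
        for v in identity_report.crc_pct.values():
            assert v == pytest.approx(100.0, abs=1e-9)
        for v in identity_report.rc.values():
            assert v == pytest.approx(1.0, abs=1e-9)
        assert identity_report.cv_bg_pct == 0.0
        assert identity_report.lung_error_pct == 0.0

    def test_background_free_omits_crc_and_lung(self, coarse_grid):
        spec = PhantomSpec.nema_iq(40.0, 0.0)
        model = ImagingSystemModel(sensitivity_cps_per_mbq=100.0, psf_fwhm_mm=0.0)
        ds = simulate_spect_volume(spec, model, coarse_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, coarse_grid)
        rep = analyze_iq(ds.images, vois, spec, None, 600.0, fit_fwhm=False)
        assert all(v is None for v in rep.crc_pct.values())
        assert rep.lung_error_pct is None

    def test_scale_invariance_with_matched_cf(self, nema_grid):
        spec = PhantomSpec.nema_iq(38.4, 4.8)
        model = ImagingSystemModel(sensitivity_cps_per_mbq=100.0, psf_fwhm_mm=0.0)
        ds = simulate_spect_volume(spec, model, nema_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, nema_grid)
        cal1 = CalibrationResult(100.0, 1.0, 1.0, 600.0, 1.0)
        rep1 = analyze_iq(ds.images, vois, spec, cal1, 600.0, fit_fwhm=False)
        scaled = {k: 3.0 * v for k, v in ds.images.items()}
        cal3 = CalibrationResult(300.0, 1.0, 1.0, 600.0, 1.0)
        rep3 = analyze_iq(scaled, vois, spec, cal3, 600.0, fit_fwhm=False)
        for d in rep1.crc_pct:
            assert rep3.crc_pct[d] == pytest.approx(rep1.crc_pct[d])
            assert rep3.rc[d] == pytest.approx(rep1.rc[d])

    def test_report_serialization(self, identity_report, tmp_path):
        identity_report.to_json(tmp_path / "r.json")
        identity_report.to_csv(tmp_path / "r.csv")
        table = identity_report.to_table()
        assert (table.metric == "crc_pct").sum() == 6

    def test_missing_photopeak_rejected(self, nema_vois):
        spec = PhantomSpec.nema_iq(38.4, 4.8)
        with pytest.raises(ValueError, match="photopeak"):
            analyze_iq({}, nema_vois, spec, None, 600.0)

    def test_counts_to_concentration_inverts_cf(self):
        cal = calibration_factor(6000.0, 1000.0, 60.0, 0.001)
        conc = counts_to_concentration(0.6, cal, 60.0, 0.1)
        # 0.6 counts/voxel over 60 s in 0.1 ml at CF 100 cps/MBq -> 0.001 MBq/ml
        assert conc == pytest.approx(0.001)
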