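"""Synthetic count-rate series, SPECT-like volumes and planar images."""

import math

import numpy as np
import pytest

from leadspect.phantoms import PhantomSpec, build_voi_set, total_activity_mbq, voi_stats
from leadspect.physics import build_window_set
from leadspect.scatter import tew_correct_volumes
from leadspect.simulate import (
    ImagingSystemModel,
    simulate_count_rate_series,
    simulate_planar,
    simulate_spect_volume,
)

from conftest import grid_for


def ideal_model(sensitivity=100.0, **overrides):
    params = dict(sensitivity_cps_per_mbq=sensitivity, psf_fwhm_mm=0.0)
    params.update(overrides)
    return ImagingSystemModel(**params)


class TestCountRateSeries:
    def test_no_dead_time_noiseless_counts(self):
        model = ideal_model(1000.0)
        series = simulate_count_rate_series(model, [2.0, 5.0], 60.0, 0, noise=False)
        assert series.points[0].counts == pytest.approx(1000.0 * 2.0 * 60.0)

    def test_expected_counts_closed_form(self):
        model = ideal_model(1000.0, tau_alpha_per_mbq=0.01)
        series = simulate_count_rate_series(model, [100.0], 120.0, 0, noise=False)
        assert series.points[0].counts == pytest.approx(1000 * 100 * math.exp(-1.0) * 120)

    def test_seed_determinism(self):
        model = ideal_model(1000.0, tau_alpha_per_mbq=0.01)
        a = simulate_count_rate_series(model, np.geomspace(1, 100, 8), 120.0, 7)
        b = simulate_count_rate_series(model, np.geomspace(1, 100, 8), 120.0, 7)
        assert all(p.counts == q.counts for p, q in zip(a.points, b.points))

    def test_empty_activities_rejected(self):
        with pytest.raises(ValueError):
            simulate_count_rate_series(ideal_model(), [], 120.0, 0)


class TestSpectVolume:
    def test_identity_pipeline_recovers_truth(self, coarse_grid):
        spec = PhantomSpec.nema_iq(40.0, 5.0)
        model = ideal_model()
        ds = simulate_spect_volume(spec, model, coarse_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, coarse_grid)
        factor = coarse_grid.voxel_volume_ml * 100.0 * 600.0  # counts per (MBq/ml)
        sphere_conc = voi_stats(ds.images["photopeak"], vois.spheres[37.0]).mean / factor
        assert sphere_conc == pytest.approx(40.0 / 1000.0, rel=1e-12)
        bg_conc = voi_stats(ds.images["photopeak"], vois.background_cylinders[0]).mean / factor
        assert bg_conc == pytest.approx(5.0 / 1000.0, rel=1e-12)

    def test_seeded_determinism_byte_identical(self, coarse_grid):
        spec = PhantomSpec.nema_iq(40.0, 5.0)
        model = ideal_model(psf_fwhm_mm=10.0, scatter_fraction=0.2)
        ws = build_window_set("Pb-212", 239)
        a = simulate_spect_volume(spec, model, coarse_grid, 600.0, 3, window_set=ws)
        b = simulate_spect_volume(spec, model, coarse_grid, 600.0, 3, window_set=ws)
        for k in a.images:
            assert a.images[k].tobytes() == b.images[k].tobytes()

    def test_partial_volume_ordering(self, coarse_grid):
        spec = PhantomSpec.nema_iq(40.0, 0.0)
        model = ideal_model(psf_fwhm_mm=14.0)
        ds = simulate_spect_volume(spec, model, coarse_grid, 600.0, 0, noise=False)
        vois = build_voi_set(spec, coarse_grid)
        means = [voi_stats(ds.images["photopeak"], vois.spheres[d]).mean for d in (10.0, 37.0)]
        assert means[0] < means[1]

    def test_count_response_non_monotone_past_peak(self):
        # doubling the fill far past the dead-time peak lowers the expected counts
        model = ideal_model(tau_alpha_per_mbq=1 / 50.0)
        spec_lo = PhantomSpec.uniform_cylinder(40.0 / 5.650)  # ~40 MBq total
        spec_hi = PhantomSpec.uniform_cylinder(150.0 / 5.650)  # ~150 MBq total
        grid = grid_for(spec_lo, 4.8)
        lo = simulate_spect_volume(spec_lo, model, grid, 600.0, 0, noise=False)
        hi = simulate_spect_volume(spec_hi, model, grid, 600.0, 0, noise=False)
        assert hi.images["photopeak"].sum() < lo.images["photopeak"].sum()

    def test_scatter_windows_support_tew(self, coarse_grid):
        spec = PhantomSpec.nema_iq(40.0, 5.0)
        model = ideal_model(psf_fwhm_mm=10.0, scatter_fraction=0.3)
        ws = build_window_set("Pb-212", 239)
        ds = simulate_spect_volume(spec, model, coarse_grid, 600.0, 5, window_set=ws)
        clean = simulate_spect_volume(
            spec, ideal_model(psf_fwhm_mm=10.0), coarse_grid, 600.0, 5, noise=False
        )
        vois = build_voi_set(spec, coarse_grid)
        corrected = tew_correct_volumes(
            ds.images["photopeak"], ds.images["lower_scatter"], ds.images["upper_scatter"], ws
        )
        mask = vois.background_cylinders[0]
        truth = voi_stats(clean.images["photopeak"], mask).total
        err_corr = abs(voi_stats(corrected, mask).total - truth)
        err_raw = abs(voi_stats(ds.images["photopeak"], mask).total - truth)
        assert err_corr < err_raw

    def test_save_writes_nifti_and_provenance(self, tmp_path):
        spec = PhantomSpec.uniform_cylinder(5.0)
        grid = grid_for(spec, 9.6)
        ds = simulate_spect_volume(spec, ideal_model(), grid, 60.0, 1)
        ds.save(tmp_path / "out")
        assert (tmp_path / "out" / "photopeak.nii").exists()
        assert (tmp_path / "out" / "truth_bq_ml.nii").exists()
        prov = (tmp_path / "out" / "provenance.json").read_text()
        assert '"seed": 1' in prov


class TestPlanar:
    def test_sensitivity_consistency(self):
        # total planar counts / (t * A) recovers the model sensitivity (Poisson SE)
        spec = PhantomSpec.uniform_cylinder(2.0)
        model = ideal_model(80.0, psf_fwhm_mm=5.0)
        views = simulate_planar(spec, model, 4.8, 300.0, 11)
        ds = views["anterior"]
        img = ds.images["photopeak"]
        total_mbq = total_activity_mbq(ds.truth_bq_ml, ds.grid)
        expected = total_mbq * 80.0 * 300.0
        assert img.sum() == pytest.approx(expected, abs=3 * math.sqrt(expected))

    def test_posterior_is_mirrored(self):
        spec = PhantomSpec.nema_iq(40.0, 5.0)
        model = ideal_model(psf_fwhm_mm=8.0)
        views = simulate_planar(spec, model, 4.8, 300.0, 2, noise=False)
        ant = views["anterior"].images["photopeak"]
        post = views["posterior"].images["photopeak"]
        assert np.allclose(post, ant[::-1, :])

    def test_axisymmetric_phantom_gives_symmetric_projection(self):
        spec = PhantomSpec.uniform_cylinder(2.0)
        views = simulate_planar(spec, ideal_model(), 4.8, 300.0, 0, noise=False)
        img = views["anterior"].images["photopeak"]
        assert np.allclose(img, img[::-1, :], rtol=1e-9, atol=1e-9)

    def test_seed_determinism(self):
        spec = PhantomSpec.uniform_cylinder(2.0)
        a = simulate_planar(spec, ideal_model(), 4.8, 300.0, 9)
        b = simulate_planar(spec, ideal_model(), 4.8, 300.0, 9)
        assert a["anterior"].images["photopeak"].tobytes() == b["anterior"].images["photopeak"].tobytes()
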