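"""Ground-truth rendering, device degradation and exposure-series generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import pbshalo as p
from pbshalo.synthetic import FILM_FIRST_SHOT_PEAK_GY, FILM_SATURATION_GY


class TestTruthImage:
    def test_gaussian_core_value_at_one_sigma(self):
        model = p.SpotModel(5.0)
        assert model.intensity(5.0, 0.0) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_grid_matches_closed_form_everywhere(self, gauss_model, gauss_truth):
        xx, yy = gauss_truth.meshgrid()
        assert np.allclose(gauss_truth.values, gauss_model.intensity(xx, yy), rtol=1e-14)

    def test_halo_model_peak_normalized(self):
        model = p.SpotModel(5.0, 0.1, 15.0)
        assert model.intensity(0.0, 0.0) == pytest.approx(1.0, abs=1e-14)

    def test_faint_tail_radius_matches_bisection_oracle(self):
        """Radius of the 1e-4 intensity level from the rendered grid agrees
        with 1D bisection on the closed form within one pixel."""
        model = p.SpotModel(5.0, 0.1, 15.0)
        pitch = 0.5
        img = p.make_truth_image(model, 5 * 15.0, pitch)
        r_oracle = brentq(lambda r: model.radial_intensity(r) - 1e-4, 0.0, 70.0)
        # scan the +x half row through the centre for the first sub-level pixel
        x, y = img.coords()
        row = img.values[np.argmin(np.abs(y)), :]
        right = x > 0
        r_grid = x[right][np.argmax(row[right] < 1e-4)]
        assert abs(r_grid - r_oracle) <= pitch

    def test_rotational_symmetry_on_grid(self, gauss_truth, truth70):
        for img in (gauss_truth, truth70):
            assert np.allclose(img.values, img.values[::-1, :], atol=1e-12)
            assert np.allclose(img.values, img.values[:, ::-1], atol=1e-12)
            assert np.allclose(img.values, img.values.T, atol=1e-12)

    @given(r=st.floats(0.1, 30.0), theta=st.floats(0.0, 2 * math.pi))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rotational_symmetry_closed_form(self, r, theta):
        model = p.SpotModel(4.0, 0.2, 9.0)
        on_axis = model.intensity(r, 0.0)
        rotated = model.intensity(r * math.cos(theta), r * math.sin(theta))
        assert rotated == pytest.approx(on_axis, rel=1e-12)

    def test_too_small_grid_raises_with_required_size(self):
        model = p.SpotModel(5.0, 0.1, 15.0)
        with pytest.raises(p.DomainError, match="75"):
            p.make_truth_image(model, 30.0)

    @pytest.mark.parametrize("kwargs", [
        {"sigma_core": -1.0},
        {"sigma_core": 5.0, "halo_weight": 1.2, "sigma_halo": 15.0},
        {"sigma_core": 5.0, "halo_weight": 0.1, "sigma_halo": 3.0},
    ])
    def test_invalid_model_parameters(self, kwargs):
        with pytest.raises(p.InvalidParameterError):
            p.SpotModel(**kwargs)


class TestRenderExposure:
    def test_ideal_device_is_identity(self, truth70):
        out = p.render_exposure(truth70, 1.0, p.ideal_device(), seed=0)
        assert np.array_equal(out.values, truth70.values)
        assert not out.saturated_mask.any()

    def test_film_first_shot_stays_unsaturated(self, truth70, film_quiet):
        out = p.render_exposure(truth70, 1.0, film_quiet)
        assert out.values.max() == pytest.approx(FILM_FIRST_SHOT_PEAK_GY)
        assert out.saturated_mask.sum() == 0

    def test_saturation_flags_match_threshold_oracle(self, truth70, film_quiet):
        """Flagged pixels are exactly those whose unclipped dose exceeds the
        film ceiling, per an independent threshold scan."""
        mag = 20.0
        out = p.render_exposure(truth70, mag, film_quiet)
        unclipped = truth70.values / truth70.values.max() * mag * FILM_FIRST_SHOT_PEAK_GY
        oracle = unclipped > FILM_SATURATION_GY
        assert oracle.sum() > 0
        assert np.array_equal(out.saturated_mask, oracle)
        assert np.all(out.values[oracle] == FILM_SATURATION_GY)

    def test_noiseless_render_restores_truth_after_unscaling(self, truth70, film_quiet):
        out = p.render_exposure(truth70, 20.0, film_quiet)
        scale = 20.0 * FILM_FIRST_SHOT_PEAK_GY / truth70.values.max()
        ok = ~out.saturated_mask
        assert np.allclose(out.values[ok] / scale, truth70.values[ok], rtol=1e-12)

    def test_faint_halo_lifted_into_range_at_400x(self, truth70, film_quiet):
        """A pixel at 0.01% of the peak is delivered at 4% of the first-shot
        peak dose in the 400x exposure — far above the clipping floor."""
        out = p.render_exposure(truth70, 400.0, film_quiet)
        rel = truth70.values / truth70.values.max()
        idx = np.unravel_index(np.argmin(np.abs(rel - 1e-4)), rel.shape)
        assert out.values[idx] / FILM_FIRST_SHOT_PEAK_GY == pytest.approx(
            0.04 * rel[idx] / 1e-4, rel=1e-6)


class TestLynxArtifact:
    def test_zero_fraction_is_identity(self, truth70):
        out = p.apply_lynx_artifact(truth70, 0.0)
        assert np.array_equal(out.values, truth70.values)

    def test_zero_image_unchanged(self):
        img = p.SpotImage(np.zeros((10, 10)), 0.5)
        out = p.apply_lynx_artifact(img, 0.4)
        assert np.array_equal(out.values, img.values)

    def test_low_dose_overresponse_reaches_ceiling_only_above_axis(self, truth70):
        out = p.apply_lynx_artifact(truth70, 0.4)
        rel = truth70.values / truth70.values.max()
        x, y = truth70.meshgrid()
        faint = (rel > 0) & (rel <= 1e-3)
        upper, lower = faint & (y > 0), faint & (y <= 0)
        assert np.allclose(out.values[upper], 1.4 * truth70.values[upper], rtol=1e-12)
        assert np.array_equal(out.values[lower], truth70.values[lower])

    def test_high_dose_region_unchanged(self, truth70):
        out = p.apply_lynx_artifact(truth70, 0.4)
        bright = truth70.values / truth70.values.max() >= 0.1
        assert np.array_equal(out.values[bright], truth70.values[bright])


class TestExposureSet:
    def test_seeded_generation_is_bit_identical(self, model70):
        a = p.make_exposure_set(model70, seed=7)
        b = p.make_exposure_set(model70, seed=7)
        for ea, eb in zip(a.exposures, b.exposures):
            assert np.array_equal(ea.values, eb.values)

    def test_different_seeds_differ(self, model70):
        a = p.make_exposure_set(model70, seed=7)
        b = p.make_exposure_set(model70, seed=8)
        assert not np.array_equal(a.exposures[0].values, b.exposures[0].values)

    @pytest.mark.parametrize("mags", [(20.0, 1.0), (1.0, 1.0), (2.0, 20.0), ()])
    def test_invalid_magnification_series_rejected(self, model70, mags):
        with pytest.raises(p.InvalidParameterError):
            p.make_exposure_set(model70, magnifications=mags, seed=0)

    def test_levels_share_grid_geometry(self, model70):
        es = p.make_exposure_set(model70, seed=0)
        assert len({e.shape for e in es.exposures}) == 1
        assert len({e.pixel_pitch for e in es.exposures}) == 1


class TestDefaultModels:
    @pytest.mark.parametrize("energy", [70, 80, 90, 100, 130])
    def test_halo_energy_models_reproduce_film_widths(self, energy):
        """At halo-dominated energies the fitted mixture crosses 50/10/1%
        exactly at the published film radii."""
        model = p.default_spot_model(energy, "Z0")
        assert model.halo_weight > 0
        fwhm, fw10, fw1 = p.FILM_WIDTHS_MM[(energy, "Z0")]
        for width, level in ((fwhm, 0.5), (fw10, 0.1), (fw1, 0.01)):
            assert model.radial_intensity(width / 2.0) == pytest.approx(level, rel=1e-4)

    @pytest.mark.parametrize("energy", [150, 180, 210, 242])
    def test_subgaussian_widths_degrade_to_single_gaussian(self, energy):
        """Published width ratios narrower than a Gaussian's cannot come from
        a core+broader-halo mixture; the model pins the FWHM instead."""
        model = p.default_spot_model(energy, "Z0")
        fwhm = p.FILM_WIDTHS_MM[(energy, "Z0")][0]
        assert model.halo_weight == 0.0
        assert model.sigma_core == pytest.approx(fwhm / p.FWHM_PER_SIGMA)

    def test_unknown_energy_rejected(self):
        with pytest.raises(p.InvalidParameterError):
            p.default_spot_model(77)
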