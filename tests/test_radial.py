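"""Radial averaging, width extraction and device comparison tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pbshalo as p
from pbshalo.radial import LYNX_MASK_DEG

GAUSS_FW = {0.5: p.FWHM_PER_SIGMA, 0.1: p.FW10_PER_SIGMA, 0.01: p.FW1_PER_SIGMA}

# Published film / scintillator FWHM columns at isocenter, by energy (mm)
TABLE1_Z0_FILM = {70: 12.5, 80: 11.5, 90: 10.7, 100: 9.8, 130: 9.5,
                  150: 9.4, 180: 9.1, 210: 9.0, 242: 8.7}
TABLE1_Z0_LYNX = {70: 12.6, 80: 11.8, 90: 11.2, 100: 10.7, 130: 9.9,
                  150: 9.5, 180: 9.2, 210: 8.7, 242: 8.7}


class TestFindCenter:
    def test_symmetric_spot_centred_at_origin(self, gauss_truth):
        cx, cy = p.find_center(gauss_truth)
        assert abs(cx) < 0.1 and abs(cy) < 0.1

    def test_offset_spot_recovered(self, shifted_truth):
        img = shifted_truth(3.0, -2.0)
        cx, cy = p.find_center(img)
        assert cx == pytest.approx(3.0, abs=0.1)
        assert cy == pytest.approx(-2.0, abs=0.1)

    def test_uniform_image_raises(self):
        with pytest.raises(p.NoPeakError):
            p.find_center(p.SpotImage(np.ones((20, 20)), 0.5))


class TestToRadial:
    def test_isotropic_profile_independent_of_interval(self, gauss_truth):
        full = p.to_radial(gauss_truth, (0, 0), (0.0, 360.0))
        wedge = p.to_radial(gauss_truth, (0, 0), LYNX_MASK_DEG)
        n = min(full.bin_radii.size, wedge.bin_radii.size)
        both = (full.pixel_counts[:n] > 0) & (wedge.pixel_counts[:n] > 0)
        ratio = full.mean_intensity[:n][both] / wedge.mean_intensity[:n][both]
        assert np.allclose(ratio, 1.0, rtol=1e-6)

    def test_pixel_counts_conserved(self, gauss_truth):
        prof = p.to_radial(gauss_truth, (0, 0), (135.0, 225.0))
        x, y = gauss_truth.meshgrid()
        theta = np.degrees(np.arctan2(y, x)) % 360.0
        inside = (theta >= 135.0) & (theta < 225.0)
        assert prof.pixel_counts.sum() == inside.sum()

    def test_artifact_quarter_mask_recovers_truth_profile(self, model70, truth70):
        """The quarter opposite the over-response reproduces the
        artifact-free profile; the full-circle average exceeds it at low
        intensity where the +y over-response lives."""
        panel = p.apply_lynx_artifact(truth70, 0.4)
        truth_prof = p.to_radial(truth70, (0, 0), LYNX_MASK_DEG)
        masked = p.to_radial(panel, (0, 0), LYNX_MASK_DEG)
        full = p.to_radial(panel, (0, 0), (0.0, 360.0))
        assert np.allclose(masked.mean_intensity, truth_prof.mean_intensity, rtol=1e-9)
        faint = truth_prof.mean_intensity < 1e-3
        assert np.all(full.mean_intensity[faint] > truth_prof.mean_intensity[faint])

    def test_empty_interval_raises(self, gauss_truth):
        with pytest.raises(p.InvalidParameterError):
            p.to_radial(gauss_truth, (0, 0), (225.0, 135.0))


class TestWidthExtraction:
    @pytest.mark.parametrize("fraction,expected", [(0.5, 11.774), (0.1, 21.460)])
    def test_gaussian_widths_match_closed_form(self, fraction, expected):
        radii = np.arange(0.0, 40.0, 0.05)
        prof = p.gaussian_reference_profile(5.0, radii)
        assert p.width_at_fraction(prof, fraction) == pytest.approx(expected, abs=0.01)

    def test_width_vanishes_near_the_peak_level(self):
        prof = p.gaussian_reference_profile(5.0, np.arange(0.0, 40.0, 0.05))
        assert p.width_at_fraction(prof, 0.999) < 0.5

    def test_level_below_grid_raises(self):
        prof = p.gaussian_reference_profile(5.0, np.arange(0.0, 8.0, 0.5))
        with pytest.raises(p.OutOfRangeError):
            p.width_at_fraction(prof, 0.01)

    @given(st.floats(0.02, 0.45), st.floats(0.5, 0.95))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_width_strictly_decreasing_in_fraction(self, f_low, f_high):
        prof = p.gaussian_reference_profile(5.0, np.arange(0.0, 40.0, 0.1))
        assert p.width_at_fraction(prof, f_low) > p.width_at_fraction(prof, f_high)

    def test_chain_recovers_gaussian_widths_within_one_bin(self, gauss_truth):
        """Full chain (render -> radial average -> interpolated crossing)
        agrees with 2 sigma sqrt(2 ln(1/f)) for f = 50%, 10%, 1%."""
        prof = p.to_radial(gauss_truth, (0, 0))
        for fraction, per_sigma in GAUSS_FW.items():
            measured = p.width_at_fraction(prof, fraction)
            assert measured == pytest.approx(5.0 * per_sigma, abs=prof.bin_width)

    def test_halo_widens_the_one_percent_width(self):
        """A 5% halo at 3x the core width pushes FW1% beyond the value a
        single Gaussian with the same FWHM would give."""
        model = p.SpotModel(4.0, 0.05, 12.0)
        img = p.make_truth_image(model, 60.0)
        prof = p.to_radial(img, (0, 0))
        fwhm = p.width_at_fraction(prof, 0.5)
        fw1 = p.width_at_fraction(prof, 0.01)
        gauss_fw1 = fwhm * math.sqrt(math.log(100.0) / math.log(2.0))
        assert fw1 > gauss_fw1 + prof.bin_width


class TestSigmaConversion:
    def test_definition(self):
        assert p.sigma_from_fwhm(p.FWHM_PER_SIGMA) == pytest.approx(1.0, abs=1e-12)

    def test_one_mm_fwhm_is_point_four_sigma(self):
        assert round(p.sigma_from_fwhm(1.0), 1) == 0.4

    def test_division(self):
        assert p.sigma_from_fwhm(12.5) == pytest.approx(5.31, abs=0.005)

    def test_non_positive_rejected(self):
        with pytest.raises(p.InvalidParameterError):
            p.sigma_from_fwhm(0.0)


class TestGaussianReference:
    def test_peak_and_one_percent_radius(self):
        sigma = 3.7
        r1 = sigma * math.sqrt(2.0 * math.log(100.0))
        prof = p.gaussian_reference_profile(sigma, np.array([0.0, r1]))
        assert prof.mean_intensity[0] == pytest.approx(1.0)
        assert prof.mean_intensity[1] == pytest.approx(0.01, rel=1e-12)

    def test_fw1_to_fwhm_ratio(self):
        assert p.FW1_PER_SIGMA / p.FWHM_PER_SIGMA == pytest.approx(2.5776, abs=1e-4)


class TestCompareDevices:
    def test_identity_gives_zero_differences(self):
        series = pd.Series(TABLE1_Z0_FILM)
        table = p.compare_devices(series, series)
        assert np.allclose(table["raw_diff_mm"], 0.0)
        assert table.loc["Mean", "percent_diff"] == pytest.approx(0.0)

    def test_published_fwhm_columns_reproduce_mean_row(self):
        table = p.compare_devices(pd.Series(TABLE1_Z0_FILM),
                                  pd.Series(TABLE1_Z0_LYNX),
                                  names=("film", "lynx"))
        assert round(table.loc["Mean", "raw_diff_mm"], 1) == -0.2
        assert round(table.loc["Mean", "percent_diff"], 1) == -2.1

    def test_mismatched_energy_sets_raise(self):
        a = pd.Series({70: 12.5, 80: 11.5})
        b = pd.Series({70: 12.6, 90: 11.2})
        with pytest.raises(p.AlignmentError):
            p.compare_devices(a, b)

    def test_dataframe_inputs_with_metric_column(self):
        film = pd.DataFrame({"energy": [70, 80], "fwhm_mm": [12.5, 11.5]})
        lynx = pd.DataFrame({"energy": [70, 80], "fwhm_mm": [12.6, 11.8]})
        table = p.compare_devices(film, lynx, "fwhm")
        assert table.loc[70, "raw_diff_mm"] == pytest.approx(-0.1)
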