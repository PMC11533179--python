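"""Linear-IR preprocessing and Gaussian band decomposition."""

import numpy as np
import pytest

from calpep import (
    BandParams,
    LinearSpectrum,
    correct_background,
    difference_spectrum,
    fit_bands,
    make_linear_spectrum,
    normalize_integral,
)

AXIS = np.arange(1500.0, 1750.0, 0.5)


class TestBackgroundCorrection:
    def test_pure_line_removed_exactly(self):
        s = LinearSpectrum(AXIS, 0.003 * AXIS + 0.7)
        out = correct_background(s)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-12)

    def test_band_center_unchanged_by_correction(self):
        band = BandParams(center=1620, sigma_inhom=8, sigma_hom=8)
        clean = make_linear_spectrum([band], AXIS)
        sloped = LinearSpectrum(AXIS, clean.absorbance + 0.002 * AXIS - 2.0)
        fit_before = fit_bands(clean, 1, [1620.0])
        fit_after = fit_bands(correct_background(sloped), 1, [1620.0])
        assert fit_after.components[0][0] == pytest.approx(
            fit_before.components[0][0], abs=0.05
        )

    def test_anchor_on_band_warns_and_flags(self):
        band = BandParams(center=1510, sigma_inhom=10, sigma_hom=10)
        s = make_linear_spectrum([band], AXIS)
        with pytest.warns(UserWarning, match="anchor"):
            out = correct_background(s)
        assert out.metadata.get("background_anchor_warning") is True

    def test_overlapping_anchor_windows_rejected(self):
        s = LinearSpectrum(AXIS, np.ones_like(AXIS))
        with pytest.raises(ValueError, match="overlap"):
            correct_background(s, [(1500, 1560), (1550, 1600)])

    def test_empty_anchor_window_rejected(self):
        s = LinearSpectrum(AXIS, np.ones_like(AXIS))
        with pytest.raises(ValueError, match="no grid points"):
            correct_background(s, [(1200, 1210), (1700, 1740)])


class TestNormalization:
    def test_integral_becomes_one(self):
        band = BandParams(center=1600, sigma_inhom=10, sigma_hom=10, amplitude=3.0)
        s = make_linear_spectrum([band], AXIS)
        out = normalize_integral(s)
        assert np.trapezoid(out.absorbance, out.wavenumbers) == pytest.approx(1.0)

    def test_scale_invariance_absorbs_path_length(self):
        band = BandParams(center=1600, sigma_inhom=10, sigma_hom=10)
        s1 = make_linear_spectrum([band], AXIS)
        s2 = LinearSpectrum(AXIS, 1.8 * s1.absorbance)
        np.testing.assert_allclose(
            normalize_integral(s1).absorbance,
            normalize_integral(s2).absorbance,
            rtol=1e-12,
        )

    def test_normalization_is_idempotent(self):
        band = BandParams(center=1600, sigma_inhom=10, sigma_hom=10)
        s = make_linear_spectrum([band], AXIS)
        once = normalize_integral(s)
        twice = normalize_integral(once)
        np.testing.assert_allclose(once.absorbance, twice.absorbance, rtol=1e-12)

    def test_nonpositive_integral_rejected(self):
        s = LinearSpectrum(AXIS, -np.ones_like(AXIS))
        with pytest.raises(ValueError, match="background"):
            normalize_integral(s)


class TestBandFits:
    def test_single_gaussian_recovered_exactly(self):
        band = BandParams(center=1617.3, sigma_inhom=9, sigma_hom=9)
        s = make_linear_spectrum([band], AXIS)
        fit = fit_bands(s, 1, [1617.3])
        assert fit.converged
        assert fit.components[0][0] == pytest.approx(1617.3, abs=0.01)

    def test_three_band_decomposition_at_one_percent_noise(self):
        bands = [
            BandParams(center=1590, sigma_inhom=8, sigma_hom=8, amplitude=1.0),
            BandParams(center=1620, sigma_inhom=7, sigma_hom=7, amplitude=0.5),
            BandParams(center=1660, sigma_inhom=8, sigma_hom=8, amplitude=0.9),
        ]
        s = make_linear_spectrum(bands, AXIS, noise_rms=0.01, seed=5)
        fit = fit_bands(s, 3, [1592.0, 1618.0, 1662.0])
        for got, want in zip(fit.centers, (1590.0, 1620.0, 1660.0)):
            assert got == pytest.approx(want, abs=1.0)

    @pytest.mark.parametrize("delta", [1.0, 7.0, 15.0])
    def test_center_shift_recovered_within_half_wavenumber(self, delta):
        """A shifted band pair resolves shifts across the amide-redshift range."""
        ref = make_linear_spectrum(
            [BandParams(center=1660, sigma_inhom=9, sigma_hom=9)],
            AXIS, noise_rms=0.01, seed=1,
        )
        shifted = make_linear_spectrum(
            [BandParams(center=1660 - delta, sigma_inhom=9, sigma_hom=9)],
            AXIS, noise_rms=0.01, seed=2,
        )
        c_ref = fit_bands(ref, 1, [1660.0]).components[0][0]
        c_shift = fit_bands(shifted, 1, [1660.0 - delta]).components[0][0]
        assert (c_ref - c_shift) == pytest.approx(delta, abs=0.5)

    def test_identical_overlapping_components_flagged_degenerate(self):
        s = make_linear_spectrum(
            [BandParams(center=1620, sigma_inhom=9, sigma_hom=9)], AXIS
        )
        fit = fit_bands(s, 2, [1620.0, 1620.0])
        assert fit.degenerate

    def test_bad_center_guess_rejected(self):
        s = make_linear_spectrum(
            [BandParams(center=1620, sigma_inhom=9, sigma_hom=9)], AXIS
        )
        with pytest.raises(ValueError, match="outside"):
            fit_bands(s, 1, [1800.0])


class TestDifferenceSpectra:
    def test_self_difference_is_zero(self):
        s = make_linear_spectrum(
            [BandParams(center=1600, sigma_inhom=10, sigma_hom=10)], AXIS
        )
        d = difference_spectrum(s, s)
        np.testing.assert_allclose(d.absorbance, 0.0)

    def test_shifted_band_gives_zero_crossing_at_midpoint(self):
        """Gaussian(c+delta) - Gaussian(c) crosses zero at c + delta/2."""
        a = make_linear_spectrum(
            [BandParams(center=1607, sigma_inhom=10, sigma_hom=10)], AXIS
        )
        b = make_linear_spectrum(
            [BandParams(center=1600, sigma_inhom=10, sigma_hom=10)], AXIS
        )
        d = difference_spectrum(a, b)
        sign_flip = np.flatnonzero(np.diff(np.sign(d.absorbance)) != 0)
        crossings = AXIS[sign_flip][
            (AXIS[sign_flip] > 1580) & (AXIS[sign_flip] < 1630)
        ]
        assert crossings.size >= 1
        np.testing.assert_allclose(crossings, 1603.5, atol=0.75)

    def test_grid_mismatch_without_interpolation_rejected(self):
        a = LinearSpectrum(AXIS, np.ones_like(AXIS))
        other = np.arange(1500.0, 1750.0, 0.7)
        b = LinearSpectrum(other, np.ones_like(other))
        with pytest.raises(ValueError, match="interpolate"):
            difference_spectrum(a, b)

    def test_disjoint_grids_rejected_even_with_interpolation(self):
        a = LinearSpectrum(AXIS, np.ones_like(AXIS))
        other = np.arange(1800.0, 1900.0, 0.5)
        b = LinearSpectrum(other, np.ones_like(other))
        with pytest.raises(ValueError, match="overlap"):
            difference_spectrum(a, b, interpolate=True)
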