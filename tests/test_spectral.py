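"""Peak detection, line assignment, dispersion fitting and FWHM measurement."""

import numpy as np
import pytest

from hsical.dispersion import DispersionModel
from hsical.errors import ConditioningError, InsufficientDataError
from hsical.spectral import (
    LineMatch,
    assign_lines,
    calibrate_from_lamp_cubes,
    detect_peaks,
    fit_dispersion,
    measure_fwhm,
)

from conftest import simulate_lamp_cubes


def gaussian(x, center, sigma, amp=1000.0):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


class TestDetectPeaks:
    def test_discrete_delta(self):
        spectrum = np.zeros(200)
        spectrum[100] = 50.0
        (peak,) = detect_peaks(spectrum, 0.1)
        assert peak.centroid == 100.0

    def test_subpixel_gaussian_against_dense_grid_oracle(self):
        # oracle: argmax of the same Gaussian evaluated on a 1e-3 px grid
        x = np.arange(300)
        spectrum = gaussian(x, 100.37, 4.0)
        fine = np.arange(90, 110, 1e-3)
        oracle = fine[np.argmax(gaussian(fine, 100.37, 4.0))]
        (peak,) = detect_peaks(spectrum, 0.1)
        assert peak.centroid == pytest.approx(oracle, abs=0.05)

    def test_blended_pair_never_oversplit(self):
        # two Gaussians 3 px apart with FWHM 10 px merge into a single blob
        x = np.arange(300)
        spectrum = gaussian(x, 148.5, 10 / 2.355) + gaussian(x, 151.5, 10 / 2.355)
        peaks = detect_peaks(spectrum, 0.05)
        assert 1 <= len(peaks) <= 2

    def test_flat_spectrum_yields_empty(self):
        assert detect_peaks(np.full(100, 7.0), 0.1) == []

    def test_input_validation(self):
        with pytest.raises(InsufficientDataError):
            detect_peaks(np.ones(3), 0.1)
        with pytest.raises(ValueError):
            detect_peaks(np.ones(100), 1.5)


class TestFitDispersion:
    def _matches_from(self, model, xs):
        return [
            LineMatch("H", model.wavelength_of_pixel(x), x, 0.5, 100.0)
            for x in xs
        ]

    def test_exact_cubic_recovered(self):
        model = DispersionModel.default_vis_nir()
        xs = np.linspace(50, 2000, 12)
        fit = fit_dispersion(self._matches_from(model, xs), n_spectral=2048)
        np.testing.assert_allclose(fit.model.coefficients, model.coefficients,
                                   rtol=1e-9, atol=1e-12)
        assert fit.max_abs_residual_nm < 1e-9

    def test_too_few_matches(self):
        model = DispersionModel.default_vis_nir()
        with pytest.raises(InsufficientDataError):
            fit_dispersion(self._matches_from(model, [100, 600, 1500]))

    def test_insufficient_span(self):
        model = DispersionModel.default_vis_nir()
        xs = np.linspace(900, 1100, 8)
        with pytest.raises(InsufficientDataError, match="span"):
            fit_dispersion(self._matches_from(model, xs), n_spectral=2048)

    def test_clustered_lines_raise_conditioning_error(self):
        matches = [
            LineMatch("H", 500.0 + 1e-9 * i, 1000.0 + 1e-9 * i, 0.5, 10.0)
            for i in range(6)
        ]
        with pytest.raises((ConditioningError, InsufficientDataError)):
            fit_dispersion(matches)

    def test_half_pixel_noise_keeps_residuals_below_half_nm(self, vis_nir_model):
        # 40+ lines with +-0.5 px centroid error: residuals stay within the
        # calibration precision of half a nanometre
        rng = np.random.default_rng(5)
        from hsical.illumination import load_line_table

        table = load_line_table()
        maxima = []
        for _ in range(5):
            matches = []
            for _, row in table.iterrows():
                x = vis_nir_model.pixel_of_wavelength(row.wavelength_air_nm)
                x += rng.uniform(-0.5, 0.5)
                matches.append(
                    LineMatch(row.species, row.wavelength_air_nm, x, 0.5, 10.0)
                )
            fit = fit_dispersion(matches, n_spectral=2048)
            maxima.append(fit.max_abs_residual_nm)
        assert max(maxima) <= 0.5

    def test_coefficient_magnitudes_match_the_instrument_regime(
        self, noiseless_lamp_cubes
    ):
        fit = calibrate_from_lamp_cubes(noiseless_lamp_cubes)
        assert fit.model.a == pytest.approx(338, abs=2)
        assert fit.model.b == pytest.approx(0.306, abs=0.01)
        assert abs(fit.model.c) < 1e-4
        assert abs(fit.model.d) < 1e-7


class TestAssignLines:
    def test_four_lamp_assignment_reaches_forty_lines(self, noisy_lamp_cubes):
        peaks = {
            sp: detect_peaks(v.mean(axis=(0, 1)), 0.02)
            for sp, v in noisy_lamp_cubes.items()
        }
        matches = assign_lines(peaks, n_spectral=2048)
        assert len(matches) >= 40

    def test_neon_needs_the_coarse_fit(self, noiseless_lamp_cubes):
        # without a provisional model (and no anchor lamps) assignment is
        # impossible; with the anchors the close neon lines resolve
        peaks = {"Ne": detect_peaks(noiseless_lamp_cubes["Ne"].mean(axis=(0, 1)),
                                    0.02)}
        with pytest.raises(InsufficientDataError):
            assign_lines(peaks, n_spectral=2048)
        full = {
            sp: detect_peaks(v.mean(axis=(0, 1)), 0.02)
            for sp, v in noiseless_lamp_cubes.items()
        }
        matches = assign_lines(full, n_spectral=2048)
        ne = [m for m in matches if m.species == "Ne"]
        assert len(ne) >= 20

    def test_unmatchable_peaks_dropped_with_log(self, noiseless_lamp_cubes, caplog):
        peaks = {
            sp: detect_peaks(v.mean(axis=(0, 1)), 0.02)
            for sp, v in noiseless_lamp_cubes.items()
        }
        from hsical.spectral import Peak

        peaks["H"] = peaks["H"] + [Peak(1234.5, 5.0, 5.0)]  # no H line there
        with caplog.at_level("INFO", logger="hsical.spectral"):
            matches = assign_lines(peaks, n_spectral=2048)
        assert all(
            not (m.species == "H" and abs(m.centroid_px - 1234.5) < 1)
            for m in matches
        )
        assert any("dropped" in r.message for r in caplog.records)


class TestMeasureFwhm:
    def test_gaussian_closed_form(self):
        # sigma = 1 nm sampled at 0.25 nm/px: FWHM = 2 sqrt(2 ln 2) = 2.3548 nm
        model = DispersionModel(400.0, 0.25, n_spectral=800)
        x = np.arange(800)
        spectrum = gaussian(x, 400.0, 1.0 / 0.25)
        res = measure_fwhm(spectrum, 400.0, model)
        assert res.fwhm_nm == pytest.approx(2.3548, abs=0.02)

    def test_hot_pixel_flagged_under_resolved(self):
        spectrum = np.zeros(100)
        spectrum[50] = 10.0
        res = measure_fwhm(spectrum, 50.0)
        assert "under-resolved" in res.flags
        assert res.fwhm_px <= 1.0

    def test_asymmetric_line_uses_both_crossings(self):
        x = np.arange(300)
        left = gaussian(x, 150.0, 3.0)
        right = gaussian(x, 150.0, 6.0)
        spectrum = np.where(x < 150, left, right)
        res = measure_fwhm(spectrum, 150.0)
        sigma_to_half = np.sqrt(2 * np.log(2))
        expected = 3.0 * sigma_to_half + 6.0 * sigma_to_half
        assert res.fwhm_px == pytest.approx(expected, abs=0.2)

    def test_truncated_flank_flagged_one_sided(self):
        x = np.arange(60)
        spectrum = gaussian(x, 2.0, 8.0)
        res = measure_fwhm(spectrum, 2.0)
        assert "one-sided" in res.flags


class TestEndToEndCalibration:
    def test_round_trip_within_half_pixel_over_seeds(self, vis_nir_model):
        # simulate -> calibrate -> compare predicted wavelengths across the
        # detector for 20 seeded noise draws
        b_half = vis_nir_model.b / 2
        x = np.linspace(0, 2047, 100)
        lam_true = vis_nir_model.wavelength_of_pixel(x)
        for seed in range(20):
            cubes = simulate_lamp_cubes(
                vis_nir_model, seed=seed, gain=2.0, read_noise=2.0, n_lines=4
            )
            fit = calibrate_from_lamp_cubes(cubes)
            err = np.abs(fit.model.wavelength_of_pixel(x) - lam_true)
            assert err.max() < b_half
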