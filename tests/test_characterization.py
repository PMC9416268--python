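"""Smile, keystone, homogeneity, temporal stability and focus consistency."""

import numpy as np
import pytest

from hsical.characterization import (
    focus_consistency,
    homogeneity,
    keystone,
    spectral_smile,
    temporal_stability,
)
from hsical.dispersion import DispersionModel
from hsical.errors import InsufficientDataError
from hsical.illumination import DriftSpec
from hsical.scenes import SceneSpec
from hsical.simulator import InstrumentConfig, simulate_scan
from hsical.spectral import mean_spectrum


@pytest.fixture(scope="module")
def vis_model():
    return DispersionModel.default_vis_nir()


def _white_cube(led_panel, model, smile_px, n_slit=600, seed=0, gain=0.0,
                n_lines=1):
    config = InstrumentConfig(n_slit=n_slit, n_spectral=model.n_spectral,
                              smile_px=smile_px, gain=gain)
    cube, _ = simulate_scan(SceneSpec.uniform(1.0), led_panel, model, config,
                            n_lines=n_lines, seed=seed)
    return cube


class TestSpectralSmile:
    def test_injected_two_pixel_smile_recovered(self, led_panel, vis_model):
        res = spectral_smile(_white_cube(led_panel, vis_model, 2.0), vis_model)
        assert res.max_abs_offset_px == pytest.approx(2.0, abs=0.3)
        assert res.max_abs_offset_nm == pytest.approx(
            2.0 * vis_model.b, abs=0.3 * vis_model.b * 2
        )

    def test_zero_smile_below_noise_floor(self, led_panel, vis_model):
        # shot noise on, 8 scan lines averaged as in a real white acquisition
        res = spectral_smile(
            _white_cube(led_panel, vis_model, 0.0, n_slit=240, seed=2,
                        gain=2.0, n_lines=16),
            vis_model,
        )
        assert res.max_abs_offset_px < 0.3
        assert res.below_pixel_size()

    @pytest.mark.parametrize("injected", [0.0, 1.0, 2.0, 5.0])
    def test_offset_estimator_unbiased(self, led_panel, vis_model, injected):
        # systematic error of the estimator, isolated from shot noise: the
        # raw (unsmoothed) per-row offsets must reproduce the injected
        # amplitude; the running average is display smoothing that
        # attenuates the quadratic tip at the slit edges
        cube = _white_cube(led_panel, vis_model, injected, n_slit=240)
        res = spectral_smile(cube, window=1)
        assert res.max_abs_offset_px - injected == pytest.approx(0.0, abs=0.1)

    def test_needs_three_peaks(self, vis_model):
        from hsical.illumination import IlluminationSpec, LedComponent

        single = IlluminationSpec(components=[LedComponent(600.0, 30.0)])
        config = InstrumentConfig(n_slit=64, n_spectral=2048)
        cube, _ = simulate_scan(SceneSpec.uniform(1.0), single, vis_model, config,
                                n_lines=1, seed=0)
        with pytest.raises(InsufficientDataError):
            spectral_smile(cube)


class TestKeystone:
    def _frame(self, led_panel, k, seed=0, gain=0.0):
        model = DispersionModel(400.0, 1.2, n_spectral=512)
        config = InstrumentConfig(n_slit=240, n_spectral=512, keystone_px=k,
                                  object_pixel_mm=0.12, gain=gain,
                                  spatial_fwhm_slit_px=2.5)
        # grid phased so edges sit near the field edge but clear of the
        # central-half boundary
        scene = SceneSpec.square_grid(5.28, offset_mm=1.2)
        cube, truth = simulate_scan(scene, led_panel, model, config,
                                    n_lines=24, seed=seed)
        row = 20  # a scan line crossing the bright-square band
        return cube.values[row], truth

    def test_five_pixel_keystone_at_field_edge(self, led_panel):
        frame, _ = self._frame(led_panel, 5.0)
        res = keystone(frame)
        assert res.max_abs_shift_px == pytest.approx(5.0, abs=0.5)
        assert res.central_half_max_px < 2.0

    def test_zero_keystone_within_precision(self, led_panel):
        res = keystone(self._frame(led_panel, 0.0)[0])
        assert res.max_abs_shift_px < 0.5

    def test_moderate_keystone_reported_below_two_px(self, led_panel):
        res = keystone(self._frame(led_panel, 1.5)[0])
        assert res.max_abs_shift_px < 2.0

    @pytest.mark.parametrize("injected", [0.0, 1.0, 2.0, 5.0])
    def test_estimator_unbiased_against_edge_geometry(self, led_panel, injected):
        # systematic error isolated from noise: the expected max shift
        # follows from the injected coefficient and the measured mid-band
        # edge positions (shift is linear in field angle)
        frame, _ = self._frame(led_panel, injected)
        res = keystone(frame)
        y_c = (240 - 1) / 2
        expected = injected * np.max(np.abs(res.edge_positions_mid - y_c)) / y_c
        assert res.max_abs_shift_px - expected == pytest.approx(0.0, abs=0.1)

    def test_needs_edges(self, led_panel, vis_model):
        flat = np.ones((64, 512))
        with pytest.raises(InsufficientDataError):
            keystone(flat)


class TestHomogeneity:
    def _slab(self, led_panel, vignetting, n_slit=200, seed=0, scale=1.0,
              gain=2.0, read_noise=1.0):
        model = DispersionModel(400.0, 1.2, n_spectral=512)
        config = InstrumentConfig(
            n_slit=n_slit, n_spectral=512, vignetting=vignetting,
            gain=gain, read_noise=read_noise, exposure_ms=20.0 * scale,
        )
        cube, _ = simulate_scan(SceneSpec.uniform(1.0), led_panel, model, config,
                                n_lines=8, seed=seed)
        return cube

    @staticmethod
    def _parabola(n, edge=0.7, center=None):
        y = np.arange(n)
        c = (n - 1) / 2 if center is None else center
        prof = 1.0 - (1.0 - edge) * ((y - c) / ((n - 1) / 2)) ** 2
        return prof / prof.max()

    def test_matching_reference_within_noise(self, led_panel):
        vig = self._parabola(200)
        res = homogeneity(self._slab(led_panel, vig), vig)
        assert res.max_relative_deviation < 0.02
        assert abs(res.peak_offset_px) < 2.0

    def test_ten_percent_tilt_detected(self, led_panel):
        tilt = np.linspace(1.0, 0.9, 200)
        res = homogeneity(self._slab(led_panel, tilt), np.ones(200))
        assert res.max_relative_deviation == pytest.approx(0.10, abs=0.02)
        assert res.skew < 0  # more light on the low-index side

    def test_decentered_profile_shifts_the_peak(self, led_panel):
        decentered = self._parabola(200, center=80.0)
        res = homogeneity(self._slab(led_panel, decentered), self._parabola(200))
        assert res.peak_offset_px == pytest.approx(80.0 - 99.5, abs=3.0)

    def test_invariant_to_exposure_scaling(self, led_panel):
        # noiseless: the spectrally integrated profile scales exactly, so
        # every normalized metric is unchanged
        vig = self._parabola(200)
        r1 = homogeneity(self._slab(led_panel, vig, seed=3, gain=0.0,
                                    read_noise=0.0), vig)
        r2 = homogeneity(self._slab(led_panel, vig, seed=3, scale=4.0, gain=0.0,
                                    read_noise=0.0), vig)
        assert r2.max_relative_deviation == pytest.approx(
            r1.max_relative_deviation, rel=1e-9
        )

    def test_reference_length_mismatch(self, led_panel):
        vig = self._parabola(200)
        with pytest.raises(ValueError, match="length"):
            homogeneity(self._slab(led_panel, vig), vig[:-3])


class TestTemporalStability:
    times = [1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0]

    def _series(self, led_panel, vis_model, drift, seed=0):
        config = InstrumentConfig(n_slit=16, n_spectral=2048, drift=drift,
                                  gain=2.0, read_noise=1.0)
        return [
            simulate_scan(SceneSpec.uniform(1.0), led_panel, vis_model, config,
                          n_lines=2, seed=seed + i, t_min=t)[0]
            for i, t in enumerate(self.times)
        ]

    def test_default_drift_warmup_around_30_min(self, led_panel, vis_model):
        series = self._series(led_panel, vis_model, DriftSpec(enabled=True))
        res = temporal_stability(series, self.times, vis_model)
        assert res.warmup_time_min == pytest.approx(30.0, abs=5.0)

    def test_shifts_below_half_nm_between_1_and_10_min(self, led_panel, vis_model):
        series = self._series(led_panel, vis_model, DriftSpec(enabled=True))
        res = temporal_stability(series, self.times, vis_model)
        first_10 = res.shifts[np.asarray(self.times) <= 10.0]
        assert np.nanmax(np.abs(first_10)) < 0.5

    def test_disabled_drift_is_flat(self, led_panel, vis_model):
        series = self._series(led_panel, vis_model, DriftSpec(enabled=False))
        res = temporal_stability(series, self.times, vis_model)
        assert np.nanmax(np.abs(res.shifts)) < 0.1
        np.testing.assert_allclose(res.intensity_ratios, 1.0, atol=0.02)

    def test_non_monotone_times_rejected(self, led_panel, vis_model):
        series = self._series(led_panel, vis_model, DriftSpec(enabled=False))
        with pytest.raises(ValueError, match="increasing"):
            temporal_stability(series[:3], [1.0, 5.0, 3.0])


class TestFocusConsistency:
    def _spectrum(self, led_panel, vis_model, fwhm_slit=0.0, seed=0, shift_nm=0.0):
        config = InstrumentConfig(n_slit=16, n_spectral=2048,
                                  spatial_fwhm_slit_px=fwhm_slit,
                                  gain=2.0, read_noise=1.0)
        model = vis_model
        if shift_nm:
            model = DispersionModel(
                vis_model.a + shift_nm, vis_model.b, vis_model.c, vis_model.d,
                n_spectral=vis_model.n_spectral,
            )
        cube, _ = simulate_scan(SceneSpec.uniform(1.0), led_panel, model, config,
                                n_lines=4, seed=seed)
        return mean_spectrum(cube.values)

    def test_identical_spectra_give_zero_deltas(self, led_panel, vis_model):
        spec = self._spectrum(led_panel, vis_model)
        res = focus_consistency(spec, spec, vis_model)
        np.testing.assert_allclose(res.deltas, 0.0, atol=1e-6)
        assert res.passed

    def test_defocus_keeps_the_spectral_axis(self, led_panel, vis_model):
        a = self._spectrum(led_panel, vis_model, seed=1)
        b = self._spectrum(led_panel, vis_model, fwhm_slit=6.0, seed=2)
        res = focus_consistency(a, b, vis_model)
        assert res.passed

    def test_injected_two_nm_shift_fails(self, led_panel, vis_model):
        a = self._spectrum(led_panel, vis_model, seed=3)
        b = self._spectrum(led_panel, vis_model, seed=4, shift_nm=-2.0)
        res = focus_consistency(a, b, vis_model)
        assert not res.passed
        assert np.median(np.abs(res.deltas)) == pytest.approx(2.0, abs=0.3)
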