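"""Forward model of the push-broom spectrograph and its illumination.

Per scan line, the detector frame (slit x spectral) is built as

    illumination(lambda) x scene reflectance x vignetting,

mapped through the cubic dispersion with a quadratic spectral-smile offset
``delta(y) = s * ((y - y_c)/y_c)^2`` (in spectral px, symmetric about slit
center) and a wavelength-linear keystone slit magnification
``m(lambda) = 1 + k * t(lambda) / y_c`` with ``t`` in [-1, 1] across the
spectral range (so a feature at the slit edge shifts by ``+-k`` px at the
extreme bands), convolved with the Gaussian slit line-spread function, and
finally degraded with scaled-Poisson shot noise and Gaussian read noise.
Discrete lamp lines are injected analytically with the same line-spread
function, so a monochromatic line lands at ``pixel_of_wavelength(lambda) +
delta(y)`` with FWHM equal to the configured slit FWHM by construction.

Every injected parameter is stored in a ground-truth record; with the same
seed the record regenerates an identical cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .cube import HyperCube
from .dispersion import DispersionModel
from .illumination import (
    DriftSpec,
    DriftState,
    IlluminationSpec,
    LampLine,
    LedComponent,
)
from .scenes import RenderedScene, SceneSpec, render_scene

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class InstrumentConfig:
    """Full parameterization of the simulated instrument.

    Noise is scaled-Poisson shot noise (``gain`` counts per photon-equivalent;
    0 disables it) plus additive Gaussian read noise.  ``scan_speed_factor``
    > 1 elongates features along the scan axis by that factor (an
    uncalibrated stage speed); ``object_pixel_mm`` is the slit-pixel pitch on
    the object plane.
    """

    n_slit: int = 256
    n_spectral: int = 2048
    pixel_pitch_um: float = 3.45
    slit_fwhm_nm: float = 2.9
    smile_px: float = 0.0
    keystone_px: float = 0.0
    vignetting: np.ndarray | None = None
    source_counts: float = 3000.0
    gain: float = 0.0
    read_noise: float = 0.0
    dark_level: float = 0.0
    drift: DriftSpec = field(default_factory=lambda: DriftSpec(enabled=False))
    scan_speed_factor: float = 1.0
    spatial_fwhm_slit_px: float = 0.0
    spatial_fwhm_scan_px: float = 0.0
    object_pixel_mm: float = 0.12
    exposure_ms: float = 20.0
    focal_length_mm: float = 17.0

    def __post_init__(self):
        if self.n_slit < 8 or self.n_spectral < 8:
            raise ValueError("detector extents must be >= 8 pixels")
        if self.slit_fwhm_nm <= 0:
            raise ValueError("slit FWHM must be > 0")
        if self.vignetting is not None:
            self.vignetting = np.asarray(self.vignetting, dtype=float)
            if self.vignetting.shape != (self.n_slit,):
                raise ValueError("vignetting profile length must equal slit extent")
            if self.vignetting.min() <= 0 or self.vignetting.max() > 1.0 + 1e-12:
                raise ValueError("vignetting values must lie in (0, 1]")

    def vignetting_profile(self) -> np.ndarray:
        if self.vignetting is None:
            return np.ones(self.n_slit)
        return self.vignetting

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vignetting"] = None if self.vignetting is None else self.vignetting.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        d = dict(d)
        if d.get("vignetting") is not None:
            d["vignetting"] = np.asarray(d["vignetting"], float)
        d["drift"] = DriftSpec(**d["drift"]) if isinstance(d.get("drift"), dict) else d.get("drift", DriftSpec(enabled=False))
        return cls(**d)


def simulate_scan(
    scene: SceneSpec,
    illum: IlluminationSpec,
    model: DispersionModel,
    config: InstrumentConfig,
    n_lines: int = 16,
    seed: int | None = 0,
    *,
    t_min: float | None = None,
    oversample: int = 4,
) -> tuple[HyperCube, dict]:
    """Simulate a push-broom scan; returns the raw cube and ground truth.

    ``t_min`` is the time since illumination power-on (minutes); ``None``
    disables warm-up drift regardless of the configured drift spec.
    """
    if model.n_spectral != config.n_spectral:
        model = DispersionModel(
            model.a, model.b, model.c, model.d,
            covariance=model.covariance, n_spectral=config.n_spectral,
        )
    drift = config.drift.state(t_min) if (t_min is not None and config.drift.enabled) else DriftState(1.0, 0.0)
    rng = np.random.default_rng(seed)

    rendered = render_scene(
        scene,
        config.object_pixel_mm,
        n_lines,
        config.n_slit,
        scan_step_mm=config.object_pixel_mm / config.scan_speed_factor,
    )
    cube = _render_counts(rendered, illum, model, config, drift, oversample)

    if config.spatial_fwhm_slit_px > 0:
        cube = gaussian_filter1d(
            cube, config.spatial_fwhm_slit_px * _SIGMA_PER_FWHM, axis=1, mode="nearest"
        )
    if config.spatial_fwhm_scan_px > 0:
        cube = gaussian_filter1d(
            cube, config.spatial_fwhm_scan_px * _SIGMA_PER_FWHM, axis=0, mode="nearest"
        )

    cube = cube + config.dark_level
    if config.gain > 0:
        cube = config.gain * rng.poisson(np.maximum(cube, 0.0) / config.gain)
    if config.read_noise > 0:
        cube = cube + rng.normal(0.0, config.read_noise, size=cube.shape)
    cube = np.maximum(cube, 0.0)

    meta = {
        "focal_length_mm": config.focal_length_mm,
        "exposure_ms": config.exposure_ms,
        "binning": 1,
        "pixel_pitch_um": config.pixel_pitch_um,
        "scan_speed_factor": config.scan_speed_factor,
    }
    truth = {
        "dispersion": {
            "a": model.a, "b": model.b, "c": model.c, "d": model.d,
            "n_spectral": model.n_spectral,
        },
        "config": config.to_dict(),
        "scene": scene.to_dict(),
        "scene_geometry": _jsonable(rendered.geometry),
        "illumination": _illum_dict(illum),
        "n_lines": int(n_lines),
        "seed": seed,
        "t_min": t_min,
        "oversample": int(oversample),
        "drift_state": {
            "intensity_scale": drift.intensity_scale,
            "wavelength_shift_nm": drift.wavelength_shift_nm,
        },
    }
    return HyperCube(cube, meta=meta), truth


def simulate_from_record(truth: dict) -> HyperCube:
    """Regenerate the identical cube from a ground-truth record."""
    disp = truth["dispersion"]
    model = DispersionModel(
        disp["a"], disp["b"], disp["c"], disp["d"], n_spectral=disp["n_spectral"]
    )
    config = InstrumentConfig.from_dict(truth["config"])
    scene = SceneSpec.from_dict(truth["scene"])
    illum = _illum_from_dict(truth["illumination"])
    cube, _ = simulate_scan(
        scene, illum, model, config,
        n_lines=truth["n_lines"], seed=truth["seed"],
        t_min=truth["t_min"], oversample=truth["oversample"],
    )
    return cube


# ------------------------------------------------------------------ internals


def _render_counts(rendered, illum, model, config, drift, oversample):
    n_slit, n_spec = config.n_slit, config.n_spectral
    n_lines = rendered.weights.shape[1]
    os = int(oversample)
    x = np.arange(n_spec, dtype=float)
    x_os = np.arange(n_spec * os, dtype=float) / os
    lam_os = model.wavelength_of_pixel(x_os)

    y = np.arange(n_slit, dtype=float)
    y_c = (n_slit - 1) / 2.0
    delta = config.smile_px * ((y - y_c) / y_c) ** 2  # spectral offset per row

    lam_x = model.wavelength_of_pixel(x)
    lam_mid = 0.5 * (lam_x[0] + lam_x[-1])
    lam_half = 0.5 * (lam_x[-1] - lam_x[0])
    t_lam = (lam_x - lam_mid) / lam_half
    m_lam = 1.0 + config.keystone_px * t_lam / y_c  # slit magnification per band

    # sampling coordinates on the (slit, spectral*os) base array
    rows = y_c + (y[:, None] - y_c) / m_lam[None, :]
    cols = (x[None, :] - delta[:, None]) * os
    coords = np.broadcast_arrays(rows, cols)

    have_continuum = len(illum.components) > 0
    if have_continuum:
        cont_os = illum.continuum(lam_os, drift) * config.source_counts
        sigma_os = (
            config.slit_fwhm_nm * _SIGMA_PER_FWHM
            / model.derivative((n_spec - 1) / 2.0) * os
        )
    rho_os = rendered.reflectance_profiles(lam_os) if have_continuum else None

    # lamp lines: precompute the slit-row-independent Gaussian footprints
    line_blocks = []
    if illum.lines:
        sigma_nm = config.slit_fwhm_nm * _SIGMA_PER_FWHM
        max_int = max(line.relative_intensity for line in illum.lines)
        lam_eff_full = None
        for line in illum.lines:
            try:
                x_line = model.pixel_of_wavelength(line.wavelength_nm)
            except Exception:
                continue  # line falls off the detector
            half = int(np.ceil(6 * sigma_nm / model.derivative(x_line)
                               + abs(config.smile_px) + 2))
            lo = max(0, int(np.floor(x_line)) - half)
            hi = min(n_spec, int(np.ceil(x_line)) + half + 1)
            if hi <= lo:
                continue
            lam_eff = model.wavelength_of_pixel(
                x[None, lo:hi] - delta[:, None]
            )  # (n_slit, window)
            amp = config.source_counts * line.relative_intensity / max_int
            gauss = amp * np.exp(
                -0.5 * ((lam_eff - line.wavelength_nm) / sigma_nm) ** 2
            )
            line_blocks.append((line, lo, hi, gauss))

    exposure_scale = config.exposure_ms / 20.0
    vig = config.vignetting_profile()
    frames = np.empty((n_lines, n_slit, n_spec))
    for i in range(n_lines):
        w_line = rendered.weights[:, i, :]  # (R, n_slit)
        if have_continuum:
            base = w_line.T @ (rho_os * cont_os[None, :])  # (n_slit, K)
            if sigma_os > 0:
                base = gaussian_filter1d(base, sigma_os, axis=1, mode="nearest")
            frame = map_coordinates(base, coords, order=1, mode="nearest")
        else:
            frame = np.zeros((n_slit, n_spec))
        for line, lo, hi, gauss in line_blocks:
            rho_l = rendered.reflectance_profiles(
                np.atleast_1d(line.wavelength_nm)
            )[:, 0]
            refl_slit = w_line.T @ rho_l  # (n_slit,)
            x_line = model.pixel_of_wavelength(line.wavelength_nm)
            m_l = np.interp(x_line, x, m_lam)
            rows_l = y_c + (y - y_c) / m_l
            refl_mapped = np.interp(rows_l, y, refl_slit)
            frame[:, lo:hi] += refl_mapped[:, None] * gauss
        frames[i] = frame * vig[:, None]
    return frames * exposure_scale


def _illum_dict(illum: IlluminationSpec) -> dict:
    return {
        "species": illum.species,
        "lines": [[l.wavelength_nm, l.relative_intensity] for l in illum.lines],
        "components": [
            [c.center_nm, c.fwhm_nm, c.relative_power, c.drift_weight]
            for c in illum.components
        ],
    }


def _illum_from_dict(d: dict) -> IlluminationSpec:
    return IlluminationSpec(
        lines=[LampLine(*row) for row in d["lines"]],
        components=[LedComponent(*row) for row in d["components"]],
        species=d.get("species"),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
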