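"""Illumination models: calibration lamps, LED panels and warm-up drift.

Calibration lamps are gas discharge tubes whose emission lines are bundled as
a reference table of air wavelengths (compiled from standard atomic spectra
tabulations, restricted to lines isolated at ~3 nm instrument resolution so
that line identification is well posed).  The broadband source is a panel of
LEDs modelled as a sum of Gaussian emitters covering 400-1000 nm.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAMP_SPECIES = ("Hg/Ar", "H", "He", "Ne")

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LampLine:
    wavelength_nm: float  # air wavelength
    relative_intensity: float


@dataclass
class LedComponent:
    center_nm: float
    fwhm_nm: float
    relative_power: float = 1.0
    #: drift of this emitter during warm-up is scaled by this factor
    drift_weight: float = 1.0


@dataclass
class IlluminationSpec:
    """Either a discrete line spectrum (lamps) or a sum of Gaussian LEDs."""

    lines: list[LampLine] = field(default_factory=list)
    components: list[LedComponent] = field(default_factory=list)
    species: str | None = None

    def __post_init__(self):
        for line in self.lines:
            if not (350.0 <= line.wavelength_nm <= 1100.0):
                raise ValueError(
                    f"lamp line {line.wavelength_nm} nm outside 350-1100 nm"
                )
            if line.relative_intensity <= 0:
                raise ValueError("line intensities must be > 0")
        for comp in self.components:
            if not (350.0 <= comp.center_nm <= 1100.0):
                raise ValueError(f"LED center {comp.center_nm} nm outside 350-1100 nm")
            if comp.relative_power <= 0 or comp.fwhm_nm <= 0:
                raise ValueError("LED power and FWHM must be > 0")

    def continuum(self, lam_nm: np.ndarray, drift: "DriftState | None" = None) -> np.ndarray:
        """Broadband spectral power density at the given wavelengths.

        Discrete lamp lines are *not* included here; the simulator injects
        them analytically with the slit line-spread function.
        """
        lam_nm = np.asarray(lam_nm, dtype=float)
        out = np.zeros_like(lam_nm)
        for comp in self.components:
            sigma = comp.fwhm_nm * _SIGMA_PER_FWHM
            scale = comp.relative_power
            shift = 0.0
            if drift is not None:
                scale *= 1.0 + (drift.intensity_scale - 1.0) * comp.drift_weight
                shift = drift.wavelength_shift_nm * comp.drift_weight
            out += scale * np.exp(
                -0.5 * ((lam_nm - comp.center_nm - shift) / sigma) ** 2
            )
        return out


def lamp_spectrum(species: str) -> IlluminationSpec:
    """Bundled emission-line list for a calibration gas-discharge tube."""
    table = load_line_table()
    if species not in LAMP_SPECIES:
        raise ValueError(
            f"unknown lamp species {species!r}; expected one of {LAMP_SPECIES}"
        )
    rows = table[table.species == species]
    lines = [
        LampLine(float(r.wavelength_air_nm), float(r.relative_intensity))
        for r in rows.itertuples()
    ]
    return IlluminationSpec(lines=lines, species=species)


def load_line_table() -> pd.DataFrame:
    """The bundled reference line table (species, wavelength_air_nm, intensity)."""
    with importlib.resources.files("hsical.data").joinpath("lamp_lines.csv").open() as f:
        return pd.read_csv(f)


def led_panel_spectrum(components: list[LedComponent] | None = None) -> IlluminationSpec:
    """Sum-of-Gaussians LED panel; the default panel covers 400-1000 nm.

    The default is a 10-emitter panel whose combined spectrum stays above 10%
    of its peak everywhere in 400-1000 nm; it is illustrative of a multi-LED
    biomedical illuminator, not a measurement of any physical panel.  NIR
    emitters carry ``drift_weight`` 1 (full warm-up drift), visible emitters
    a reduced weight, reflecting the stronger warm-up of NIR LEDs.
    """
    if components is None:
        components = default_led_panel()
    if len(components) == 0:
        raise ValueError("LED panel needs at least one component")
    return IlluminationSpec(components=list(components))


def default_led_panel() -> list[LedComponent]:
    # 60 nm spacing with 45 nm FWHM keeps the summed spectrum everywhere
    # above 10% of its peak while leaving each emitter a distinct maximum
    centers = [405, 465, 525, 585, 645, 705, 765, 825, 885, 945, 1005]
    fwhms = [45, 45, 45, 45, 45, 45, 45, 45, 45, 45, 50]
    powers = [0.8, 1.0, 1.1, 1.0, 0.95, 0.9, 1.0, 0.95, 0.85, 0.9, 0.85]
    return [
        LedComponent(c, f, p, drift_weight=1.0 if c >= 700 else 0.3)
        for c, f, p in zip(centers, fwhms, powers)
    ]


# ---------------------------------------------------------------- drift


@dataclass
class DriftSpec:
    """Exponential warm-up of the LED source.

    Peak intensity decays as ``I(t) = I_inf + (I0 - I_inf) * exp(-t/tau)``
    with ``I0 = 1``; the emission wavelength shifts by
    ``shift0_nm * exp(-t/tau)`` relative to the fully warmed state, i.e. the
    shift observed between two times decays with the same time constant.
    Defaults give a ~30 min warm-up under the criterion "relative intensity
    change < 1% per 10 min".
    """

    tau_min: float = 20.0
    intensity_drop: float = 0.10      # I0 - I_inf
    shift0_nm: float = 0.4            # wavelength offset at t=0 vs warmed state
    enabled: bool = True

    def state(self, t_min: float) -> "DriftState":
        if t_min < 0:
            raise ValueError("time must be >= 0")
        if not self.enabled:
            return DriftState(1.0, 0.0)
        decay = float(np.exp(-t_min / self.tau_min))
        i_inf = 1.0 - self.intensity_drop
        return DriftState(
            intensity_scale=i_inf + self.intensity_drop * decay,
            wavelength_shift_nm=self.shift0_nm * decay,
        )


@dataclass
class DriftState:
    intensity_scale: float
    wavelength_shift_nm: float


def drift_state(drift: DriftSpec, t_min: float) -> DriftState:
    """Illumination intensity scale and wavelength shift ``t_min`` after power-on."""
    return drift.state(t_min)
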