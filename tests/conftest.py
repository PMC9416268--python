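"""Shared fixtures: simulated lamp acquisitions and instrument defaults.

Session-scoped fixtures cache the more expensive simulator runs so the
suite stays fast; everything is generated in memory from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsical.dispersion import DispersionModel
from hsical.illumination import lamp_spectrum, led_panel_spectrum
from hsical.scenes import SceneSpec
from hsical.simulator import InstrumentConfig, simulate_scan

LAMP_SPECIES = ("Hg/Ar", "H", "He", "Ne")


@pytest.fixture(scope="session")
def vis_nir_model() -> DispersionModel:
    """The instrument's cubic dispersion (~338-1027 nm over 2048 px)."""
    return DispersionModel.default_vis_nir()


@pytest.fixture(scope="session")
def led_panel():
    return led_panel_spectrum()


def simulate_lamp_cubes(
    model: DispersionModel,
    *,
    n_slit: int = 16,
    n_lines: int = 8,
    seed: int = 0,
    gain: float = 0.0,
    read_noise: float = 0.0,
    slit_fwhm_nm: float = 2.9,
) -> dict[str, np.ndarray]:
    """One raw cube of counts per calibration-lamp species."""
    config = InstrumentConfig(
        n_slit=n_slit, n_spectral=model.n_spectral, slit_fwhm_nm=slit_fwhm_nm,
        gain=gain, read_noise=read_noise,
    )
    scene = SceneSpec.uniform(1.0)
    cubes = {}
    for k, species in enumerate(LAMP_SPECIES):
        cube, _ = simulate_scan(
            scene, lamp_spectrum(species), model, config,
            n_lines=n_lines, seed=seed * 37 + k,
        )
        cubes[species] = cube.values
    return cubes


@pytest.fixture(scope="session")
def noiseless_lamp_cubes(vis_nir_model):
    return simulate_lamp_cubes(vis_nir_model)


@pytest.fixture(scope="session")
def noisy_lamp_cubes(vis_nir_model):
    return simulate_lamp_cubes(vis_nir_model, gain=2.0, read_noise=2.0, seed=1)
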