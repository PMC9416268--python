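# hsical

Calibration, characterization and verification of push-broom hyperspectral
imaging (HSI) systems, with a forward instrument simulator.

Biomedical HSI instruments — line-scan spectrographs imaging tissue over
400–1000 nm — only produce quantitative, cross-comparable data after a
rigorous protocol: calibrate the spectral and spatial axes against
references, characterize the real resolutions and the illumination, measure
the optical aberrations (smile, keystone, vignetting), and verify the whole
chain against a trusted spectrometer. `hsical` implements that protocol as
a library plus CLI, and bundles a forward model of the instrument so every
estimator can be exercised — and its accuracy measured — against known
ground truth without hardware.

## What it computes

**Spectral axis.** The pixel-to-wavelength map of the spectrograph is a
cubic in the 0-based spectral pixel index *x*:

    λ(x) = a + b·x + c·x² + d·x³

fitted by ordinary least squares to gas-discharge lamp lines (Hg/Ar, H, He,
Ne; air wavelengths bundled) that are identified iteratively: a provisional
fit from the unambiguous mercury and hydrogen lines, then nearest-reference
matching of all ~64 lines within a ±1.5 nm window. Spectral resolution is
the FWHM of a narrow line from interpolated half-maximum crossings.

**Spatial axis.** Printed Ronchi gratings give the object-plane pixel pitch
(mm/px) from sub-pixel bar-edge spacings; a USAF1951 target gives the
resolving power as the finest three-bar element with Michelson contrast
≥ 0.1 on every gap, per axis (frequency `2^(group + (element−1)/6)` lp/mm,
bar width `w = 1/(2f)`); a square grid calibrates the scanning speed
(elongation % and corrective factor).

**Aberrations and stability.** Spectral smile (per-slit-pixel wavelength
offset of the illumination peaks, running-average 50 smoothing), keystone
(band-to-band bar-edge shifts on a single frame), illumination homogeneity
versus the lens relative-illumination curve, LED warm-up drift (exponential
fit; warm-up = time to < 1 % intensity change per 10 min), and out-of-focus
spectral consistency.

**Verification.** Transmittance of ink-filled sample cells is reduced to a
normalized absorbance

    Ã(λ) = −ln(T(λ)·a) / max[−ln(T(λ)·a)]

whose shape is instrument-independent; the normalization factor *a* is
fitted by bounded 1-D search. An erythema-index map
`E = log₁₀(R_red / R_green)` demonstrates the application level.

**Simulator.** The forward model renders scenes (Ronchi, USAF1951, square
grid, uniform slabs, two-region samples) through cubic dispersion, a
Gaussian slit line-spread function, quadratic smile, wavelength-linear
keystone, vignetting, a 10+ LED illumination panel, exponential warm-up
drift, scan-speed error, and scaled-Poisson + Gaussian noise, and records
every injected parameter as ground truth.

## Worked example

Calibrate the spectral axis from simulated four-lamp acquisitions:

```python
from hsical import (DispersionModel, InstrumentConfig, SceneSpec,
                    lamp_spectrum, simulate_scan, calibrate_from_lamp_cubes)

truth = DispersionModel.default_vis_nir()           # a, b, c, d ground truth
config = InstrumentConfig(n_slit=16, n_spectral=2048, gain=2.0, read_noise=2.0)

cubes = {}
for i, species in enumerate(["Hg/Ar", "H", "He", "Ne"]):
    cube, _ = simulate_scan(SceneSpec.uniform(1.0), lamp_spectrum(species),
                            truth, config, n_lines=4, seed=i)
    cubes[species] = cube.values

fit = calibrate_from_lamp_cubes(cubes)
print(f"a = {fit.model.a:.1f} nm,  b = {fit.model.b:.4f} nm/px")
print(f"c = {fit.model.c:.2e} nm/px^2,  d = {fit.model.d:.2e} nm/px^3")
print(f"{fit.n_lines} lines matched, max |residual| = {fit.max_abs_residual_nm:.3f} nm")
```

prints

```
a = 337.7 nm,  b = 0.3060 nm/px
c = 2.60e-05 nm/px^2,  d = -5.42e-09 nm/px^3
64 lines matched, max |residual| = 0.120 nm
```

— the injected dispersion (337.7 nm intercept, 0.306 nm/px linear term) is
recovered from 64 identified lines with a tenth-of-a-nanometre worst-case
residual under shot and read noise.

The full protocol runs from the shell and writes one JSON report with a
pass/fail summary against the configured thresholds:

```sh
hsical run-all --seed 1 --out protocol_out
hsical fixtures --kind lamps --seed 1 --out fixtures/lamps   # ENVI cubes + ground truth
```

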