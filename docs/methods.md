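# Methods

## Instrument model

A push-broom system acquires one spatial line and the full spectral axis
per frame; scanning builds the second spatial axis. The canonical cube is
indexed `(scan_line, slit_pixel, spectral_pixel)`, 0-based.

The spectrograph's pixel-to-wavelength map is a third-order expansion
`λ(x) = a + b·x + c·x² + d·x³` with `a` in nm, `b` in nm/px, `c` in
nm/px², `d` in nm/px³. The default operating point is
`a = 337.7, b = 0.306, c = 2.6·10⁻⁵, d = −5.4·10⁻⁹` over 2048 spectral
pixels, i.e. ~338–1027 nm — a typical VIS–NIR biomedical configuration.
The map must be strictly increasing over the detector; this is checked
numerically at construction. The model is agnostic to the physical origin
of the cubic (unknown grating/prism geometry); it only assumes smoothness
and monotonicity.

The forward simulator composes, per scan line:

1. **Scene** — targets rasterized on the object plane with area-averaged
   (supersampled) region boundaries, so edges are band-limited the way a
   printed edge imaged onto a detector is. Geometry ground truth (periods,
   bar/gap centers) is recorded for estimator round-trips.
2. **Illumination** — either discrete lamp lines (bundled air-wavelength
   tables) or a sum-of-Gaussians LED panel. The default panel has emitters
   every 60 nm with 45 nm FWHM from 405 to 1005 nm: the summed spectrum
   stays above 10 % of its peak across 400–1000 nm while each emitter keeps
   a distinct maximum (needed by the smile and stability estimators). It is
   illustrative of a multi-LED illuminator, not a measurement of any
   physical panel.
3. **Dispersion + aberrations** — smile as a quadratic spectral-pixel
   offset `δ(y) = s·((y−y_c)/y_c)²` symmetric about slit center (only the
   bound of real smile is typically known, not its shape; a quadratic bow
   is the generic low-order form); keystone as a wavelength-linear slit
   magnification `m(λ) = 1 + k·t(λ)/y_c`, `t ∈ [−1,1]` across the spectral
   range, so a feature at the slit edge shifts by ±k px at the extreme
   bands — matching how keystone is measured (edge shifts on one frame).
4. **Slit line-spread function** — Gaussian with configurable FWHM in nm
   (default 2.9 nm). The broadband path is convolved on a 4× oversampled
   spectral grid; discrete lamp lines are injected analytically, so a
   monochromatic line lands at `pixel_of_wavelength(λ) + δ(y)` with the
   configured FWHM by construction.
5. **Vignetting, exposure, drift** — per-slit-pixel relative illumination
   in (0,1]; counts linear in exposure; LED warm-up drift
   `I(t) = I∞ + (I0−I∞)·exp(−t/τ)` with the wavelength shift decaying with
   the same τ. Defaults `τ = 20 min`, intensity drop 10 %, initial shift
   0.4 nm were chosen so that the warm-up criterion (< 1 % intensity change
   per 10 min) is crossed near 30 min and the shift between 1 and 10 min
   stays below 0.5 nm — the stability behaviour expected of NIR LEDs, which
   drift more than visible ones (`drift_weight` 1.0 vs 0.3).
6. **Noise** — scaled-Poisson shot noise (`gain` counts per
   photon-equivalent; 0 disables) plus additive Gaussian read noise. Every
   stochastic call takes a seed; the ground-truth record regenerates the
   identical cube.

### What the simulator does not emulate

No physical-optics diffraction, polarization, stray light, detector
nonlinearity/saturation, wavelength-dependent spatial PSF, or non-ideal
(printed-paper) target edges. Passing round-trip tests therefore
demonstrates the estimators' correctness and precision under the modelled
effects, not the absolute performance of any physical instrument; absolute
resolving-power numbers in particular are only matched via configured
PSFs.

## Estimators

**Peak centroiding.** Emission peaks are found by prominence (fraction of
the spectrum maximum, default 0.02) and refined by 3-point log-parabolic
interpolation — exact for a sampled Gaussian, robust at the ~3-px-wide
peaks a slit-limited spectrograph produces. Under a cubic dispersion the
line is Gaussian in wavelength, not in pixel index, so centroids carry a
deterministic bias at the 10⁻³ px level; coefficients are therefore
recovered exactly (≲10⁻⁹) only for a linear map, and to ≲0.02 nm in
predicted wavelength for the default cubic.

**Line identification** is two-stage because neon/argon lines a few nm
apart are ambiguous without an estimated wavelength: (1) the brightest
mercury/argon and hydrogen lines are paired with the brightest tabulated
lines in intensity rank order (pairs violating monotonicity are dropped via
a longest-increasing-subsequence filter) and a provisional cubic is fitted;
(2) all peaks are mapped through the provisional model, matched to the
nearest reference within ±1.5 nm (≈5 px, wide enough after a coarse fit to
split close doublets, tight enough to reject neighbours), refitted, and
re-matched once so lines initially outside the window are recovered.
The bundled tables keep only lines ≥ ~3 nm from a stronger same-species
neighbour, since closer pairs blend at the instrument's resolution and
would corrupt sub-pixel centroids.

**Dispersion fit.** OLS of reference wavelength on `{1, x, x², x³}` with
the pixel coordinate scaled to O(1) for conditioning; coefficient
covariance from the residual variance; requires ≥4 lines spanning ≥1/3 of
the detector. A condition number above 10¹⁰ raises a conditioning error.

**FWHM** from linearly interpolated half-maximum crossings on both flanks
independently (so asymmetric lines get the true crossing-to-crossing
width), converted to nm via the local dispersion `b + 2cx + 3dx²`. Flags:
`one-sided` (flank never reaches half max), `under-resolved` (≤1 px).

**Edges** (pitch, keystone, scan aspect) at the 50 %-amplitude crossing
with amplitude bounded by the 5th/95th percentiles — invariant to global
intensity scale and contrast inversion. "Discernible" on the USAF target
means Michelson contrast ≥ 0.1 on every inter-bar gap (no standard
criterion exists; 0.1 is configurable and recorded in the report).
Slit- and scan-axis resolving powers are evaluated independently, since the
entrance slit limits one and the detector pitch the other.

**Peak tracking** (smile, temporal stability, focus) uses windowed
normalized cross-correlation against a reference spectrum (slit-center row,
or the first time point), refined by Gauss–Newton least-squares
registration of the window against the linearly interpolated reference.
NCC is bounded by 1 and attained only on a perfect match, so broad LED
plateaus cannot drag the maximum to a lag boundary; the Gauss–Newton step
returns exactly zero for identical inputs and averages noise over the whole
window, which plain 3-point interpolation of a flat correlation apex does
not. Both reference and signal are pre-smoothed with the same 3-px Gaussian
so shot-noise ripples on plateaus neither spawn spurious peaks nor bias the
registration asymmetrically.

**Smile** offsets are reported per slit pixel after subtracting the
slit-center value and applying a centered running average of 50 elements
(edge handling by window truncation). The smoothing attenuates the
quadratic tip at the slit edges by a known geometric factor (≈9 % at 600
slit pixels); the unsmoothed offsets (`window=1`) are the unbiased
estimator and are what the round-trip property tests check.

**Keystone** is measured on a single frame: per band, each edge's shift
relative to its mid-band position; bands with contrast below 10 % of the
frame-wide amplitude are skipped with a logged count. The maximum over the
central half of the slit uses the open middle interval of mid-band edge
positions. With the wavelength-linear model a 5-px edge keystone implies up
to 2.5 px at the central-half boundary, so grids for round-trip tests are
phased to keep edges clear of that boundary. A ~2.5-px spatial PSF is
included in round-trip scenes; perfectly hard edges resampled by linear
interpolation otherwise show a small (+0.02 px/px) pixel-locking bias in
the crossing position.

**Homogeneity** compares the spectrally integrated, peak-normalized slit
profile to the lens relative-illumination curve: sub-pixel peak offset
(quadratic fit on a smoothed profile), maximum relative deviation
`max|I/ref − 1|`, and skew (normalized first moment about slit center). All
metrics are invariant to exposure scale by construction.

**Warm-up** is the earliest time at which a single-exponential fit to the
most-drifting peak's intensity predicts < 1 % change per 10-minute
interval (solved by bracketed root finding on the fitted curve).

**Normalized absorbance.** As printed, dividing `ln(T·a)` by its maximum is
sign-ambiguous for T < 1; the implementation uses `A = −ln(T·a)` normalized
by its maximum so the strongest absorption equals exactly 1, and records
the sign convention in the output. The normalization factor is fitted by
bounded scalar minimization of the RMSE over `a ∈ [0.5, 2]` (tolerance
10⁻⁶). A continuity-offset utility removes the reference spectrometer's
detector-switch step at a stated wavelength (default 860 nm) by offsetting
the NIR segment to meet the extrapolated visible segment; the exact
smoothing used by dual-detector instruments varies, so this is a documented
generic stand-in.

**Erythema index** is `log₁₀(R_red/R_green)` so that redder (more
perfused) tissue scores higher; an `invert` flag flips the ratio. Band
defaults 540/650 nm are conventional green/red picks and are parameters,
not claims.

## Protocol orchestration

Stages run strictly in the order spectral → spatial → characterize →
verify; verification requires a completed spectral calibration, and
characterization downgrades to pixel units when run without one. All
thresholds (contrast 0.1, line tolerance 1.5 nm, reflectance clip 1.5,
warm-up 1 %/10 min, focus pass 1 nm) live in a versioned YAML config with
these defaults. Every stage derives its seed from the master seed, the
report schema is stable (stage keys present even when skipped), and
identical config + seed reproduce the report byte-for-byte apart from the
timestamp.

Dark frames are optional everywhere (an absent dark equals an all-zero
dark); white/dark stacks are scan-averaged before normalization.
Reflectance above 1 is clipped at 1.5 rather than masked so specular pixels
stay visible in maps; a mask channel records clipped and invalid pixels.

## Problem sizes

Simulated acquisitions use the full 2048-px spectral axis with 16 slit
pixels for lamp work (spectra are slit-uniform), 240–600 slit pixels for
smile/keystone/homogeneity, and a 16× spectrally binned axis (128 or 64
bands) for spatial targets, whose geometry does not depend on spectral
sampling. Scan extents are 24–260 lines as each target requires (≥3
periods, full USAF layouts). These sizes were chosen so every estimator
sees the geometry it needs while the whole suite and the acceptance script
run in well under a minute each.

## Known limitations

- Keystone and smile are measured, never corrected or resampled.
- The pixel-index convention of the dispersion fit is 0-based and
  self-consistent; fits of the same physical instrument with a different
  index origin differ by a re-indexing shift, so agreement is asserted at
  the level of predicted wavelengths, not raw coefficients.
- `c` and `d` are carried in nm/px² and nm/px³; reports print them in
  those units.
- The ENVI dialect is the minimal header+BIL little-endian form this
  package writes; arbitrary third-party ENVI variants (other interleaves,
  byte orders, data types beyond float32/64) are rejected with explicit
  errors rather than guessed at.
- Vacuum↔air wavelength conversion is out of scope; the bundled tables are
  air wavelengths.
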