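"""Verification against a reference spectrometer and application-level indices.

System-level verification images a well-characterized absorber (ink-filled
sample cells) in transmission and compares against a laboratory
spectrometer.  Because cell thickness, concentration and collection
efficiency differ between instruments, absolute transmittances are not
comparable; instead both are reduced to a *normalized absorbance*

    A~(lambda) = -ln(T(lambda) * a) / max[-ln(T(lambda) * a)]

whose shape and peak positions are modality independent.  The normalization
factor ``a`` absorbs the different amounts of collected light and is found
by fitting.  By construction the strongest absorption maps to exactly 1 and
the curve is invariant to any ``(s, 1/s)`` rescaling of ``(T, a)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .cube import HyperCube, ReflectanceCube
from .errors import DegenerateInputError, WavelengthRangeError

__all__ = [
    "TransmittanceSpectrum", "NormalizedAbsorbance", "transmittance",
    "normalized_absorbance", "fit_normalization_factor",
    "detector_switch_correction", "erythema_index", "write_index_map",
]


@dataclass
class TransmittanceSpectrum:
    """A transmittance curve on a strictly increasing wavelength grid."""

    wavelength_nm: np.ndarray
    T: np.ndarray
    masked: np.ndarray | None = None   # bands unusable (zero blank)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.wavelength_nm.shape != self.T.shape:
            raise ValueError("wavelength grid and T must have equal length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "TransmittanceSpectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=_csv_header_rows(path))
        return cls(data[:, 0], data[:, 1])


def _csv_header_rows(path) -> int:
    with open(path) as f:
        first = f.readline()
    try:
        float(first.split(",")[0])
        return 0
    except ValueError:
        return 1


@dataclass
class NormalizedAbsorbance:
    """Absorbance scaled so the strongest absorption equals 1.

    Sign convention: ``A = -ln(T * a)``, so absorbing features are positive;
    recorded in ``sign_convention`` for output metadata.
    """

    wavelength_nm: np.ndarray
    A: np.ndarray
    factor: float
    sign_convention: str = "-ln(T*a), maximum absorption = 1"


def transmittance(
    sample_cube: HyperCube,
    blank_cube: HyperCube,
    region: tuple[slice, slice] | None = None,
    *,
    region_size: int = 20,
) -> TransmittanceSpectrum:
    """Per-band transmittance averaged over a spatially homogeneous region.

    ``region`` is an (scan, slit) slice pair; by default a centered
    ``region_size x region_size`` (20 x 20) window is used.  Bands where the
    blank is zero anywhere in the region are reported masked, not NaN.
    """
    if sample_cube.wavelength_nm is None:
        raise WavelengthRangeError("sample cube needs a wavelength axis")
    if region is None:
        region = _centered_region(sample_cube, region_size)
    s = sample_cube.values[region[0], region[1], :]
    b = blank_cube.values[region[0], region[1], :]
    if s.size == 0 or b.size == 0:
        raise ValueError("region selects no pixels")
    bad = np.any(b <= 0, axis=(0, 1))
    b_safe = np.where(b <= 0, 1.0, b)
    T = (s / b_safe).mean(axis=(0, 1))
    T = np.where(bad, np.nan, T)
    return TransmittanceSpectrum(sample_cube.wavelength_nm, T, masked=bad)


def _centered_region(cube: HyperCube, size: int) -> tuple[slice, slice]:
    s0 = max((cube.n_scan - size) // 2, 0)
    s1 = max((cube.n_slit - size) // 2, 0)
    return (
        slice(s0, min(s0 + size, cube.n_scan)),
        slice(s1, min(s1 + size, cube.n_slit)),
    )


def normalized_absorbance(
    T: TransmittanceSpectrum, a: float = 1.0
) -> NormalizedAbsorbance:
    """Compute ``A~ = -ln(T*a) / max(-ln(T*a))``.

    Raises :class:`DegenerateInputError` when nothing absorbs (max A <= 0),
    since the normalization would be sign-ambiguous.
    """
    valid = np.isfinite(T.T)
    if np.any(T.T[valid] * a <= 0):
        raise ValueError("T*a must be > 0 wherever the logarithm is taken")
    A = np.full_like(T.T, np.nan)
    A[valid] = -np.log(T.T[valid] * a)
    peak = np.nanmax(A)
    if not np.isfinite(peak) or peak <= 0:
        raise DegenerateInputError(
            "no absorption anywhere (max A <= 0); cannot normalize"
        )
    return NormalizedAbsorbance(T.wavelength_nm, A / peak, float(a))


@dataclass
class AgreementRecord:
    factor: float
    rmse: float
    peak_deltas_nm: np.ndarray     # per-feature peak-wavelength differences


def fit_normalization_factor(
    T_test: TransmittanceSpectrum,
    A_ref: NormalizedAbsorbance,
    bounds: tuple[float, float] = (0.5, 2.0),
) -> AgreementRecord:
    """Fit the normalization factor ``a`` to a reference normalized absorbance.

    Minimizes the RMSE between ``normalized_absorbance(T_test, a)`` and the
    reference over the common wavelength grid with a bounded 1-D search.
    Also reports per-feature peak-wavelength deltas (for each local maximum
    of the reference above half height, the distance to the nearest test
    peak).
    """
    lo = max(T_test.wavelength_nm[0], A_ref.wavelength_nm[0])
    hi = min(T_test.wavelength_nm[-1], A_ref.wavelength_nm[-1])
    if hi <= lo:
        raise WavelengthRangeError("test and reference spectra do not overlap")
    sel = (T_test.wavelength_nm >= lo) & (T_test.wavelength_nm <= hi)
    sel &= np.isfinite(T_test.T)
    grid = T_test.wavelength_nm[sel]
    T_common = TransmittanceSpectrum(grid, T_test.T[sel])
    ref_interp = np.interp(grid, A_ref.wavelength_nm, A_ref.A)

    def rmse(a: float) -> float:
        A = normalized_absorbance(T_common, a).A
        return float(np.sqrt(np.nanmean((A - ref_interp) ** 2)))

    res = minimize_scalar(rmse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-6})
    a_fit = float(res.x)
    A_fit = normalized_absorbance(T_common, a_fit).A
    deltas = _peak_deltas(grid, ref_interp, A_fit)
    return AgreementRecord(a_fit, rmse(a_fit), deltas)


def _peak_deltas(grid, ref, test):
    from scipy.signal import find_peaks

    ref_pk, _ = find_peaks(ref, height=0.5 * np.nanmax(ref))
    test_pk, _ = find_peaks(test, height=0.5 * np.nanmax(test))
    if len(ref_pk) == 0 or len(test_pk) == 0:
        return np.array([])
    out = []
    for rp in ref_pk:
        tp = test_pk[np.argmin(np.abs(grid[test_pk] - grid[rp]))]
        out.append(grid[tp] - grid[rp])
    return np.asarray(out)


def detector_switch_correction(
    spectrum: TransmittanceSpectrum, switch_nm: float = 860.0
) -> TransmittanceSpectrum:
    """Remove the reference spectrometer's detector-switch discontinuity.

    Dual-detector spectrometers change sensors at a fixed wavelength, leaving
    a step in the curve.  Values below the switch are kept and a constant
    offset is added to the segment at and above it so the curve is continuous
    at the switch wavelength.
    """
    lam, T = spectrum.wavelength_nm, spectrum.T.copy()
    nir = lam >= switch_nm
    vis = ~nir
    if not nir.any() or not vis.any():
        return TransmittanceSpectrum(lam, T)
    # extrapolate the visible segment to the first NIR sample
    last = np.flatnonzero(vis)[-1]
    if last >= 1:
        slope = (T[last] - T[last - 1]) / (lam[last] - lam[last - 1])
    else:
        slope = 0.0
    first_nir = np.flatnonzero(nir)[0]
    expected = T[last] + slope * (lam[first_nir] - lam[last])
    T[nir] += expected - T[first_nir]
    return TransmittanceSpectrum(lam, T)


def write_index_map(index_map: np.ndarray, path, metadata: dict | None = None):
    """Write a 2-D index map as a single-band float TIFF plus JSON metadata."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(index_map, dtype=np.float32))
    meta = {"shape": list(index_map.shape), "dtype": "float32"}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def erythema_index(
    cube: ReflectanceCube,
    green_band: float = 540.0,
    red_band: float = 650.0,
    *,
    invert: bool = False,
) -> np.ndarray:
    """Erythema-index map: ``E = log10(R_red / R_green)`` per pixel.

    The log band ratio of red over green reflectance is a standard proxy for
    tissue blood content — haemoglobin absorbs green strongly, so redder
    (more perfused) tissue scores higher.  ``invert=True`` flips the ratio.
    Pixels with zero reflectance in either band are returned as NaN; the
    ratio makes the map invariant to uniform illumination scaling.
    """
    from .cube import extract_band

    r_green = extract_band(cube, green_band)
    r_red = extract_band(cube, red_band)
    if invert:
        r_green, r_red = r_red, r_green
    valid = (r_green > 0) & (r_red > 0)
    out = np.full(r_green.shape, np.nan)
    out[valid] = np.log10(r_red[valid] / r_green[valid])
    return out
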