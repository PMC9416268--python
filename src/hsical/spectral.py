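"""Wavelength-axis calibration from gas-lamp spectra.

The calibration is iterative because some species (neon, argon) emit lines a
few nm apart that cannot be identified without an estimated central
wavelength.  Stage 1 builds a provisional cubic from the unambiguous lamps
(mercury/argon and hydrogen) by pairing the brightest detected peaks with the
brightest tabulated lines in rank order; stage 2 maps every detected peak to
a predicted wavelength through the provisional model, matches each to the
nearest tabulated line within a tolerance window (default +-1.5 nm), refits,
and repeats the match/fit once so lines mis-window-ed by the provisional
model are recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .dispersion import DispersionModel
from .errors import ConditioningError, InsufficientDataError
from .illumination import lamp_spectrum

logger = logging.getLogger(__name__)

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Peak:
    """A detected emission peak with sub-pixel centroid."""

    centroid: float       # fractional spectral pixel
    height: float         # counts at the discrete maximum
    prominence: float

    def __float__(self):
        return self.centroid


@dataclass
class LineMatch:
    """A detected centroid paired with a tabulated reference line."""

    species: str
    reference_nm: float   # air wavelength
    centroid_px: float
    centroid_sigma_px: float
    intensity: float

    def __post_init__(self):
        if not (350.0 <= self.reference_nm <= 1100.0):
            raise ValueError(
                f"reference wavelength {self.reference_nm} nm outside 350-1100 nm"
            )


@dataclass
class CalibrationFit:
    """Result of the cubic dispersion fit."""

    model: DispersionModel
    matches: list[LineMatch]
    residuals_nm: np.ndarray      # reference - fitted, per line

    @property
    def n_lines(self) -> int:
        return len(self.matches)

    @property
    def max_abs_residual_nm(self) -> float:
        return float(np.max(np.abs(self.residuals_nm)))

    @property
    def rms_residual_nm(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_nm**2)))

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                "a_nm": self.model.a,
                "b_nm_per_px": self.model.b,
                "c_nm_per_px2": self.model.c,
                "d_nm_per_px3": self.model.d,
            },
            "coefficient_errors": self.model.coefficient_errors.tolist(),
            "n_lines": self.n_lines,
            "max_abs_residual_nm": self.max_abs_residual_nm,
            "rms_residual_nm": self.rms_residual_nm,
            "residuals_nm": self.residuals_nm.tolist(),
        }


def detect_peaks(
    spectrum: np.ndarray, min_prominence: float = 0.02
) -> list[Peak]:
    """Locate emission peaks with sub-pixel centroids.

    Discrete maxima are found by prominence (as a fraction of the spectrum
    maximum) and refined by 3-point log-parabolic interpolation, which is
    exact for a sampled Gaussian.  A flat spectrum yields an empty list.
    Blended lines that produce a single discrete maximum are returned as one
    peak — never split.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.size < 5:
        raise InsufficientDataError("spectrum must have at least 5 samples")
    if not (0.0 < min_prominence < 1.0):
        raise ValueError("min_prominence must be in (0, 1)")
    top = spectrum.max()
    if top <= 0 or np.ptp(spectrum) == 0:
        return []
    idx, props = find_peaks(spectrum, prominence=min_prominence * top)
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        peaks.append(Peak(_refine(spectrum, i), float(spectrum[i]), float(prom)))
    peaks.sort(key=lambda p: p.centroid)
    return peaks


def _refine(spectrum: np.ndarray, i: int) -> float:
    if i == 0 or i == len(spectrum) - 1:
        return float(i)
    y0, y1, y2 = spectrum[i - 1], spectrum[i], spectrum[i + 1]
    if min(y0, y1, y2) > 0:
        a, b, c = np.log(y0), np.log(y1), np.log(y2)
    else:
        a, b, c = y0, y1, y2
    denom = a - 2 * b + c
    if denom >= 0:  # not a local curvature maximum; keep discrete location
        return float(i)
    return float(i + 0.5 * (a - c) / denom)


def assign_lines(
    peaks: dict[str, list[Peak]],
    references=None,
    coarse: DispersionModel | None = None,
    *,
    tolerance_nm: float = 1.5,
    n_spectral: int | None = None,
) -> list[LineMatch]:
    """Iteratively identify detected peaks against the bundled line lists.

    ``peaks`` maps species name to the peaks detected in that lamp's
    spectrum.  When no ``coarse`` model is given, the unambiguous species
    (``Hg/Ar`` and ``H``) must be present to bootstrap the provisional fit.
    Unmatched peaks are dropped with a logged count.
    """
    if references is None:
        references = {sp: lamp_spectrum(sp) for sp in peaks}
    if coarse is None:
        coarse = _bootstrap_model(peaks, references, n_spectral)

    model = coarse
    matches: list[LineMatch] = []
    for _ in range(2):  # match -> fit -> rematch -> (final fit by caller)
        matches = _match_with_model(peaks, references, model, tolerance_nm)
        if len(matches) < 4:
            raise InsufficientDataError(
                f"only {len(matches)} line matches; cubic dispersion needs >= 4"
            )
        model = _fit_core(matches, n_spectral).model
    return matches


def _bootstrap_model(peaks, references, n_spectral):
    anchor_species = [sp for sp in ("Hg/Ar", "H") if sp in peaks and peaks[sp]]
    if not anchor_species:
        raise InsufficientDataError(
            "no coarse model given and no Hg/Ar or H lamp available to bootstrap"
        )
    pairs: list[tuple[float, float, str, float]] = []
    for sp in anchor_species:
        refs = sorted(
            references[sp].lines, key=lambda l: l.relative_intensity, reverse=True
        )
        pk = sorted(peaks[sp], key=lambda p: p.height, reverse=True)
        k = min(len(refs), len(pk), 6)
        pairs += [
            (pk[j].centroid, refs[j].wavelength_nm, sp, pk[j].height)
            for j in range(k)
        ]
    # dispersion is monotone: discard rank-pairing mistakes by keeping the
    # longest subsequence with wavelength increasing in pixel order
    pairs.sort(key=lambda t: t[0])
    keep = _longest_increasing([t[1] for t in pairs])
    pairs = [pairs[i] for i in keep]
    if len(pairs) < 4:
        raise InsufficientDataError(
            f"bootstrap pairing produced only {len(pairs)} consistent lines"
        )
    matches = [
        LineMatch(sp, lam, x, 0.5, height) for x, lam, sp, height in pairs
    ]
    return _fit_core(matches, n_spectral).model


def _match_with_model(peaks, references, model, tolerance_nm):
    matches: list[LineMatch] = []
    n_dropped = 0
    for sp, pk_list in peaks.items():
        refs = references[sp].lines
        ref_lams = np.array([l.wavelength_nm for l in refs])
        claimed: dict[int, LineMatch] = {}
        for pk in pk_list:
            lam_pred = model.wavelength_of_pixel(pk.centroid)
            j = int(np.argmin(np.abs(ref_lams - lam_pred)))
            err = abs(ref_lams[j] - lam_pred)
            if err > tolerance_nm:
                n_dropped += 1
                continue
            cand = LineMatch(sp, float(ref_lams[j]), pk.centroid, 0.5, pk.height)
            prev = claimed.get(j)
            if prev is None or err < abs(
                ref_lams[j] - model.wavelength_of_pixel(prev.centroid_px)
            ):
                if prev is not None:
                    n_dropped += 1
                claimed[j] = cand
            else:
                n_dropped += 1
        matches += list(claimed.values())
    if n_dropped:
        logger.info("assign_lines: dropped %d unmatched/duplicate peaks", n_dropped)
    matches.sort(key=lambda m: m.centroid_px)
    return matches


def _longest_increasing(seq):
    """Indices of the longest strictly increasing subsequence."""
    n = len(seq)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    i = int(np.argmax(best_len))
    out = []
    while i >= 0:
        out.append(i)
        i = prev[i]
    return out[::-1]


def fit_dispersion(
    matches: list[LineMatch], n_spectral: int | None = None
) -> CalibrationFit:
    """Ordinary least squares of reference wavelength on {1, x, x^2, x^3}.

    Coefficient covariance comes from the residual variance.  Requires at
    least 4 matches; when ``n_spectral`` is given the centroids must span at
    least a third of the detector so the cubic is well conditioned.
    """
    if len(matches) < 4:
        raise InsufficientDataError(
            f"cubic dispersion fit needs >= 4 lines; got {len(matches)}"
        )
    x = np.array([m.centroid_px for m in matches])
    if n_spectral is not None and np.ptp(x) < n_spectral / 3.0:
        raise InsufficientDataError(
            f"matched lines span {np.ptp(x):.0f} px, less than a third of the "
            f"detector ({n_spectral} px); the cubic would be poorly constrained"
        )
    return _fit_core(matches, n_spectral)


def _fit_core(matches, n_spectral):
    x = np.array([m.centroid_px for m in matches])
    lam = np.array([m.reference_nm for m in matches])
    scale = max(np.abs(x).max(), 1.0)
    design = np.vander(x / scale, 4, increasing=True)
    cond = np.linalg.cond(design)
    if cond > 1e10:
        raise ConditioningError(
            f"dispersion design matrix ill conditioned (cond={cond:.3g}); "
            "line positions are too clustered",
            condition_number=cond,
        )
    coef_s, _, _, _ = np.linalg.lstsq(design, lam, rcond=None)
    fitted = design @ coef_s
    residuals = lam - fitted
    dof = len(matches) - 4
    sigma2 = float(residuals @ residuals) / dof if dof > 0 else 0.0
    cov_s = sigma2 * np.linalg.inv(design.T @ design)
    powers = scale ** np.arange(4)
    coef = coef_s / powers
    cov = cov_s / np.outer(powers, powers)
    n_spec = n_spectral if n_spectral is not None else int(np.ceil(x.max())) + 1
    model = DispersionModel(*coef, covariance=cov, n_spectral=n_spec)
    return CalibrationFit(model=model, matches=list(matches), residuals_nm=residuals)


@dataclass
class FwhmResult:
    fwhm_nm: float | None
    fwhm_px: float
    flags: list[str]

    @property
    def ok(self) -> bool:
        return not self.flags


def measure_fwhm(
    spectrum: np.ndarray,
    centroid: float,
    model: DispersionModel | None = None,
    *,
    window: int = 50,
) -> FwhmResult:
    """Full width at half maximum of one line, by interpolated half-max crossings.

    Both flanks are located independently by linear interpolation, so an
    asymmetric line yields the true crossing-to-crossing width rather than a
    symmetric fit.  The pixel width converts to nm through the local
    dispersion ``b + 2cx + 3dx^2`` when a model is given.  Flags:
    ``one-sided`` when a flank never reaches half max inside the window,
    ``under-resolved`` when the width collapses to <= 1 px.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    i0 = int(round(centroid))
    i0 = min(max(i0, 0), len(spectrum) - 1)
    lo = max(0, i0 - window)
    hi = min(len(spectrum), i0 + window + 1)
    seg = spectrum[lo:hi]
    base = float(seg.min())
    peak = float(spectrum[i0])
    half = base + 0.5 * (peak - base)
    flags: list[str] = []

    def _cross(direction: int) -> float | None:
        j = i0
        while lo <= j + direction < hi:
            nxt = j + direction
            if spectrum[nxt] < half <= spectrum[j]:
                frac = (spectrum[j] - half) / (spectrum[j] - spectrum[nxt])
                return j + direction * frac
            j = nxt
        return None

    left = _cross(-1)
    right = _cross(+1)
    if left is None and right is None:
        return FwhmResult(None, 0.0, ["one-sided", "under-resolved"])
    if left is None or right is None:
        flags.append("one-sided")
        side = right - centroid if left is None else centroid - left
        width_px = 2.0 * side
    else:
        width_px = right - left
    if width_px <= 1.0:
        flags.append("under-resolved")
    fwhm_nm = None
    if model is not None:
        fwhm_nm = width_px * model.derivative(centroid)
    return FwhmResult(fwhm_nm, float(width_px), flags)


def mean_spectrum(values: np.ndarray) -> np.ndarray:
    """Average a raw cube's counts over scan lines and slit rows."""
    return np.asarray(values).mean(axis=(0, 1))


def calibrate_from_lamp_cubes(
    cubes: dict[str, np.ndarray],
    *,
    min_prominence: float = 0.02,
    tolerance_nm: float = 1.5,
    n_spectral: int | None = None,
) -> CalibrationFit:
    """End-to-end spectral calibration from one raw cube per lamp species."""
    peaks = {
        sp: detect_peaks(mean_spectrum(v), min_prominence) for sp, v in cubes.items()
    }
    if n_spectral is None:
        n_spectral = next(iter(cubes.values())).shape[-1]
    matches = assign_lines(
        peaks, tolerance_nm=tolerance_nm, n_spectral=n_spectral
    )
    return fit_dispersion(matches, n_spectral=n_spectral)
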