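"""Aberration and stability metrics: smile, keystone, homogeneity, drift, focus.

These estimators quantify artifacts the spectrograph and illumination
introduce; per the protocol's scope they measure, but never resample or
correct, the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .cube import HyperCube
from .dispersion import DispersionModel
from .errors import InsufficientDataError
from .spatial import edge_positions
from .spectral import Peak, detect_peaks, _refine, mean_spectrum

logger = logging.getLogger(__name__)


def _corr_shift(
    signal: np.ndarray,
    template: np.ndarray,
    start: int,
    max_lag: int,
) -> float:
    """Sub-pixel shift of ``signal[start:start+len(template)]`` vs ``template``.

    Normalized cross-correlation over integer lags (bounded by 1, attained
    only on a perfect match, so trends and plateaus cannot drag the maximum
    to a boundary) seeds a Gauss-Newton sub-pixel registration.  Returns NaN
    when the window leaves the signal.
    """
    n_t = len(template)
    lo, hi = start - max_lag, start + n_t + max_lag
    if lo < 0 or hi > len(signal):
        return float("nan")
    seg = signal[lo:hi]
    t = template - template.mean()
    t_norm = np.linalg.norm(t)
    if t_norm == 0:
        return float("nan")
    corr = np.empty(2 * max_lag + 1)
    for i in range(2 * max_lag + 1):
        s = seg[i:i + n_t]
        s = s - s.mean()
        denom = np.linalg.norm(s) * t_norm
        corr[i] = (s @ t) / denom if denom > 0 else 0.0
    apex = int(np.argmax(corr))
    if apex == 0 or apex == len(corr) - 1:
        return float(apex - max_lag)
    # Gauss-Newton sub-pixel registration: model the signal window as
    # a * ref(x - delta) + b with ref linearly interpolated; exactly zero
    # for identical windows and noise-efficient on broad flat features
    grid = np.arange(len(seg), dtype=float)
    grad = np.gradient(seg, edge_order=2)
    j = np.arange(n_t, dtype=float)
    delta = float(apex - max_lag)
    for _ in range(12):
        pos = j + max_lag + delta
        s_d = np.interp(pos, grid, seg)
        g_d = np.interp(pos, grid, grad)
        s_c = s_d - s_d.mean()
        denom = float(s_c @ s_c)
        if denom == 0:
            break
        a_fit = float(s_c @ t) / denom
        if a_fit == 0:
            break
        r = t - a_fit * s_c
        jac = a_fit * (g_d - g_d.mean())
        jj = float(jac @ jac)
        if jj == 0:
            break
        step = float(r @ jac) / jj
        delta += step
        if abs(delta) > max_lag:
            delta = float(np.clip(delta, -max_lag, max_lag))
            break
        if abs(step) < 1e-6:
            break
    return delta


def _illum_peaks(
    spectrum: np.ndarray, min_prominence: float, smooth_sigma: float = 3.0
) -> tuple[np.ndarray, list[Peak]]:
    """Detect broadband-illumination peaks on a lightly smoothed spectrum.

    LED emission bumps are tens of pixels wide, so a 3-px Gaussian smoothing
    suppresses shot-noise ripples (which otherwise register as spurious
    peaks on plateaus) without moving the real maxima.  Returns the smoothed
    spectrum (used as the correlation reference) and the peaks.
    """
    from scipy.ndimage import gaussian_filter1d

    smooth = gaussian_filter1d(np.asarray(spectrum, float), smooth_sigma)
    return smooth, detect_peaks(smooth, min_prominence)


class _PeakTracker:
    """Tracks illumination peaks across rows/times by windowed correlation."""

    def __init__(
        self,
        reference: np.ndarray,
        peaks: list[Peak],
        max_lag: int = 10,
        smooth_sigma: float = 3.0,
    ):
        from .spectral import measure_fwhm

        self.reference = np.asarray(reference, float)
        self.max_lag = int(max_lag)
        self.smooth_sigma = smooth_sigma
        self.windows: list[tuple[int, np.ndarray, float]] = []
        for pk in peaks:
            width = measure_fwhm(self.reference, pk.centroid).fwhm_px
            width = max(width, 3.0)
            hw = int(np.clip(round(1.5 * width), 5, 80))
            c = int(round(pk.centroid))
            lo = max(c - hw, self.max_lag)
            hi = min(c + hw + 1, len(self.reference) - self.max_lag)
            if hi - lo < 5:
                self.windows.append((lo, np.array([]), pk.centroid))
                continue
            self.windows.append((lo, self.reference[lo:hi].copy(), pk.centroid))

    def shifts(self, signal: np.ndarray) -> np.ndarray:
        """Per-peak spectral shift of ``signal`` relative to the reference."""
        from scipy.ndimage import gaussian_filter1d

        if self.smooth_sigma > 0:
            # same kernel as the reference so identical inputs give shift 0
            signal = gaussian_filter1d(np.asarray(signal, float), self.smooth_sigma)
        out = np.empty(len(self.windows))
        for p, (lo, template, _) in enumerate(self.windows):
            if template.size == 0:
                out[p] = np.nan
                continue
            out[p] = _corr_shift(signal, template, lo, self.max_lag)
        return out


# ------------------------------------------------------------------ smile


@dataclass
class SmileResult:
    slit_px: np.ndarray               # slit coordinate of each profile sample
    offsets_px: np.ndarray            # (n_peaks, n_slit) smoothed offsets
    offsets_nm: np.ndarray | None     # same, via local dispersion (if model given)
    peak_centroids: np.ndarray        # spectral-pixel centroid of each tracked peak

    @property
    def max_abs_offset_px(self) -> float:
        return float(np.nanmax(np.abs(self.offsets_px)))

    @property
    def max_abs_offset_nm(self) -> float | None:
        if self.offsets_nm is None:
            return None
        return float(np.nanmax(np.abs(self.offsets_nm)))

    def below_pixel_size(self) -> bool:
        """True when the measured smile is smaller than one spectral pixel."""
        return self.max_abs_offset_px < 1.0


def spectral_smile(
    uniform_cube: HyperCube,
    model: DispersionModel | None = None,
    *,
    window: int = 50,
    min_prominence: float = 0.05,
    max_lag: int = 10,
) -> SmileResult:
    """Per-slit-pixel spectral offset of the illumination peaks.

    Requires a spatially uniform scene (white/PTFE slab) lit by a source with
    at least 3 identifiable peaks.  Each peak's spectral position at every
    slit row is measured by windowed cross-correlation against the slit
    center row, the value at slit center is subtracted, and the offset
    profile is smoothed with a centered running average of ``window``
    elements (truncated at the slit edges).
    """
    spectra = uniform_cube.values.mean(axis=0)  # (slit, spectral)
    n_slit = spectra.shape[0]
    center_row = n_slit // 2
    ref_smooth, ref_peaks = _illum_peaks(spectra[center_row], min_prominence)
    if len(ref_peaks) < 3:
        raise InsufficientDataError(
            f"only {len(ref_peaks)} illumination peaks found; smile needs >= 3"
        )
    tracker = _PeakTracker(ref_smooth, ref_peaks, max_lag=max_lag)
    offsets = np.full((len(ref_peaks), n_slit), np.nan)
    for y in range(n_slit):
        offsets[:, y] = tracker.shifts(spectra[y])
    offsets -= offsets[:, center_row][:, None]
    smoothed = np.vstack([_running_mean(o, window) for o in offsets])
    centroids0 = np.array([pk.centroid for pk in ref_peaks])
    offsets_nm = None
    if model is not None:
        offsets_nm = smoothed * model.derivative(centroids0)[:, None]
    return SmileResult(
        slit_px=np.arange(n_slit),
        offsets_px=smoothed,
        offsets_nm=offsets_nm,
        peak_centroids=centroids0,
    )


def _running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running average with edge handling by window truncation."""
    kernel = np.ones(window)
    num = np.convolve(np.nan_to_num(values), kernel, mode="same")
    den = np.convolve(np.isfinite(values).astype(float), kernel, mode="same")
    out = num / np.where(den > 0, den, 1.0)
    out[den == 0] = np.nan
    return out


# ------------------------------------------------------------------ keystone


@dataclass
class KeystoneResult:
    band_index: np.ndarray
    shifts_px: np.ndarray             # (n_bands, n_edges), NaN where skipped
    edge_positions_mid: np.ndarray    # slit px of each tracked edge at mid-band
    n_skipped_bands: int
    n_slit: int

    @property
    def max_abs_shift_px(self) -> float:
        return float(np.nanmax(np.abs(self.shifts_px)))

    @property
    def central_half_max_px(self) -> float:
        lo, hi = self.n_slit * 0.25, self.n_slit * 0.75
        sel = (self.edge_positions_mid >= lo) & (self.edge_positions_mid <= hi)
        if not sel.any():
            return float("nan")
        return float(np.nanmax(np.abs(self.shifts_px[:, sel])))


def keystone(
    grid_frame: np.ndarray,
    *,
    contrast_threshold: float = 0.1,
    match_tolerance_px: float = 10.0,
) -> KeystoneResult:
    """Edge-shift-vs-wavelength profile on a single hyperspectral frame.

    ``grid_frame`` is one scan line, shape (slit, spectral), of a high
    contrast bar/grid scene.  At every spectral band each bar edge (50%
    crossing) is localized; its shift relative to the mid-band position is
    the keystone deformation.  Bands whose profile contrast falls below
    ``contrast_threshold`` (relative to the frame-wide amplitude) are skipped
    with a logged count.
    """
    frame = np.asarray(grid_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("grid_frame must be 2-D (slit, spectral)")
    n_slit, n_bands = frame.shape
    mid = n_bands // 2
    ref_edges = edge_positions(frame[:, mid])
    if len(ref_edges) < 2:
        raise InsufficientDataError(
            "mid-band profile shows fewer than 2 edges; keystone needs a grid scene"
        )
    global_amp = float(np.percentile(frame, 95) - np.percentile(frame, 5))
    shifts = np.full((n_bands, len(ref_edges)), np.nan)
    n_skipped = 0
    for b in range(n_bands):
        profile = frame[:, b]
        amp = float(np.percentile(profile, 95) - np.percentile(profile, 5))
        if amp < contrast_threshold * global_amp:
            n_skipped += 1
            continue
        edges = edge_positions(profile)
        if len(edges) == 0:
            n_skipped += 1
            continue
        for e, ref in enumerate(ref_edges):
            j = int(np.argmin(np.abs(edges - ref)))
            if abs(edges[j] - ref) <= match_tolerance_px:
                shifts[b, e] = edges[j] - ref
    if n_skipped:
        logger.info("keystone: skipped %d low-contrast bands", n_skipped)
    return KeystoneResult(
        band_index=np.arange(n_bands),
        shifts_px=shifts,
        edge_positions_mid=ref_edges,
        n_skipped_bands=n_skipped,
        n_slit=n_slit,
    )


# ------------------------------------------------------------------ homogeneity


@dataclass
class HomogeneityResult:
    normalized_intensity: np.ndarray   # per slit pixel, max = 1
    reference_curve: np.ndarray        # normalized reference, max = 1
    peak_offset_px: float              # measured peak minus reference peak
    max_relative_deviation: float      # max |I/ref - 1|
    skew: float                        # normalized first moment about slit center


def homogeneity(
    slab_cube: HyperCube | list[HyperCube], reference_curve: np.ndarray
) -> HomogeneityResult:
    """Spatial illumination homogeneity versus a lens relative-illumination curve.

    ``slab_cube`` is a uniform-slab acquisition (or a stack of them, which is
    averaged).  The spectrally integrated intensity per slit pixel is
    normalized to its maximum and compared to the (equally normalized)
    reference curve: the sub-pixel peak-position offset, the maximum relative
    deviation and the profile skew are reported.  The metrics are invariant
    to global exposure scaling by construction.
    """
    cubes = slab_cube if isinstance(slab_cube, (list, tuple)) else [slab_cube]
    if len(cubes) < 1:
        raise InsufficientDataError("need at least one slab cube")
    profile = np.mean(
        [c.values.mean(axis=0).sum(axis=1) for c in cubes], axis=0
    )
    reference_curve = np.asarray(reference_curve, dtype=float)
    if reference_curve.shape != profile.shape:
        raise ValueError(
            f"reference curve length {reference_curve.shape[0]} does not match "
            f"slit extent {profile.shape[0]}"
        )
    norm = profile / profile.max()
    ref = reference_curve / reference_curve.max()
    peak_offset = _subpixel_argmax(norm) - _subpixel_argmax(ref)
    deviation = float(np.max(np.abs(norm / ref - 1.0)))
    y = np.arange(norm.size)
    y_c = (norm.size - 1) / 2.0
    skew = float(np.sum(norm * (y - y_c)) / (np.sum(norm) * y_c))
    return HomogeneityResult(norm, ref, float(peak_offset), deviation, skew)


def _subpixel_argmax(profile: np.ndarray) -> float:
    """Noise-robust sub-pixel peak position of a broad illumination profile.

    The profile is smoothed (running mean, ~5% of its length) and a quadratic
    is fitted around the discrete maximum; the vertex is the peak position.
    """
    n = profile.size
    smooth = _running_mean(profile.astype(float), max(n // 20, 1))
    i = int(np.nanargmax(smooth))
    hw = max(n // 10, 2)
    lo, hi = max(0, i - hw), min(n, i + hw + 1)
    x = np.arange(lo, hi, dtype=float)
    coeffs = np.polyfit(x, smooth[lo:hi], 2)
    if coeffs[0] >= 0:
        return float(i)
    vertex = -coeffs[1] / (2 * coeffs[0])
    return float(np.clip(vertex, lo, hi - 1))


# ------------------------------------------------------------------ stability


@dataclass
class StabilityResult:
    times_min: np.ndarray
    peak_centroids_px: np.ndarray     # (n_peaks,) at the first time point
    shifts: np.ndarray                # (n_times, n_peaks) vs first, px or nm
    intensity_ratios: np.ndarray      # (n_times, n_peaks) vs first
    shift_units: str                  # "px" or "nm"
    warmup_time_min: float | None     # from the exponential fit
    fit_params: dict = field(default_factory=dict)

    def table(self) -> list[dict]:
        rows = []
        for i, t in enumerate(self.times_min):
            rows.append({
                "t_min": float(t),
                "shift": self.shifts[i].tolist(),
                "intensity_ratio": self.intensity_ratios[i].tolist(),
            })
        return rows


def temporal_stability(
    white_refs: list[HyperCube],
    times_min: np.ndarray,
    model: DispersionModel | None = None,
    *,
    min_prominence: float = 0.05,
    max_lag: int = 10,
    stability_criterion: float = 0.01,
    criterion_interval_min: float = 10.0,
) -> StabilityResult:
    """Wavelength and intensity drift of the illumination during warm-up.

    For every illumination peak, the spectral shift (windowed correlation
    against the first acquisition) and the intensity ratio relative to the
    first time point are tabulated.  The warm-up time is the earliest time at
    which a single-exponential fit to the most-drifting peak's intensity
    predicts a relative change below ``stability_criterion`` (default 1%)
    per ``criterion_interval_min`` (default 10 min).
    """
    times = np.asarray(times_min, dtype=float)
    if len(white_refs) != len(times):
        raise ValueError("one time stamp per cube required")
    if len(times) < 3:
        raise InsufficientDataError("temporal stability needs >= 3 time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    spectra = [mean_spectrum(c.values) for c in white_refs]
    ref_smooth, ref_peaks = _illum_peaks(spectra[0], min_prominence)
    if not ref_peaks:
        raise InsufficientDataError("no illumination peaks found")
    n_p = len(ref_peaks)
    tracker = _PeakTracker(ref_smooth, ref_peaks, max_lag=max_lag)
    centroids0 = np.array([pk.centroid for pk in ref_peaks])
    shifts_px = np.empty((len(times), n_p))
    heights = np.empty((len(times), n_p))
    for i, spec in enumerate(spectra):
        shifts_px[i] = tracker.shifts(spec)
        pos = np.clip(np.round(centroids0 + shifts_px[i]), 0, len(spec) - 1)
        heights[i] = spec[pos.astype(int)]
    shifts_px -= shifts_px[0]
    ratios = heights / heights[0]
    centroids = centroids0[None, :] + shifts_px
    if model is not None:
        shifts = shifts_px * model.derivative(centroids0)[None, :]
        units = "nm"
    else:
        shifts, units = shifts_px, "px"

    # exponential warm-up fit on the peak with the largest intensity change
    worst = int(np.argmax(np.ptp(ratios, axis=0)))
    warmup, params = _fit_warmup(
        times, heights[:, worst], stability_criterion, criterion_interval_min
    )
    return StabilityResult(
        times_min=times,
        peak_centroids_px=centroids[0],
        shifts=shifts,
        intensity_ratios=ratios,
        shift_units=units,
        warmup_time_min=warmup,
        fit_params=params,
    )


def _fit_warmup(times, intensity, criterion, interval):
    def expo(t, i_inf, amp, tau):
        return i_inf + amp * np.exp(-t / tau)

    i0, i_end = intensity[0], intensity[-1]
    p0 = (i_end, i0 - i_end, max(times[-1] / 3.0, 1.0))
    try:
        popt, _ = curve_fit(expo, times, intensity, p0=p0, maxfev=20000)
    except RuntimeError:
        return None, {}
    i_inf, amp, tau = popt
    params = {"i_inf": float(i_inf), "amplitude": float(amp), "tau_min": float(tau)}
    if tau <= 0 or abs(amp) < 1e-9 * max(abs(i_inf), 1e-12):
        return 0.0, params

    def rel_change(t):
        now, later = expo(t, *popt), expo(t + interval, *popt)
        return abs(now - later) / max(abs(now), 1e-300) - criterion

    if rel_change(0.0) <= 0:
        return 0.0, params
    t_hi = times[-1] * 10 + 10 * tau
    if rel_change(t_hi) > 0:
        return None, params
    return float(brentq(rel_change, 0.0, t_hi)), params


# ------------------------------------------------------------------ focus


@dataclass
class FocusResult:
    matched_centroids_px: np.ndarray   # (n, 2): in-focus, displaced
    deltas: np.ndarray                 # per matched peak, px or nm
    delta_units: str
    n_unmatched: int
    passed: bool
    partial: bool


def focus_consistency(
    spectrum_in_focus: np.ndarray,
    spectrum_displaced: np.ndarray,
    model: DispersionModel | None = None,
    *,
    min_prominence: float = 0.05,
    match_tolerance_px: float = 10.0,
    pass_threshold_nm: float = 1.0,
) -> FocusResult:
    """Peak-wavelength agreement between in-focus and displaced acquisitions.

    Defocus broadens the optical spot but must not move the spectral axis;
    matched peak centroids are compared and the test passes when every
    |delta| stays below ``pass_threshold_nm`` (the system's wavelength
    uncertainty; in px when no model is given).  Peaks present in only one
    spectrum make the result partial, with the matched subset reported.
    """
    spec_a = np.asarray(spectrum_in_focus, float)
    spec_b = np.asarray(spectrum_displaced, float)
    smooth_a, pk_a = _illum_peaks(spec_a, min_prominence)
    _, pk_b = _illum_peaks(spec_b, min_prominence)
    if len(pk_a) < 3 or len(pk_b) < 3:
        raise InsufficientDataError("focus comparison needs >= 3 peaks per spectrum")
    cent_b = np.array([p.centroid for p in pk_b])
    tracker = _PeakTracker(smooth_a, pk_a, max_lag=int(np.ceil(match_tolerance_px)))
    shifts = tracker.shifts(spec_b)
    pairs = []
    used = set()
    n_unmatched = 0
    for pa, shift in zip(pk_a, shifts):
        j = int(np.argmin(np.abs(cent_b - pa.centroid)))
        if (
            np.isfinite(shift)
            and abs(cent_b[j] - pa.centroid) <= match_tolerance_px
            and j not in used
        ):
            pairs.append((pa.centroid, pa.centroid + shift))
            used.add(j)
        else:
            n_unmatched += 1
    n_unmatched += len(pk_b) - len(used)
    if not pairs:
        raise InsufficientDataError("no common peaks between the two spectra")
    matched = np.array(pairs)
    deltas_px = matched[:, 1] - matched[:, 0]
    if model is not None:
        deltas = deltas_px * model.derivative(matched[:, 0])
        units = "nm"
        threshold = pass_threshold_nm
    else:
        deltas, units, threshold = deltas_px, "px", pass_threshold_nm
    return FocusResult(
        matched_centroids_px=matched,
        deltas=deltas,
        delta_units=units,
        n_unmatched=n_unmatched,
        passed=bool(np.all(np.abs(deltas) < threshold)),
        partial=n_unmatched > 0,
    )
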