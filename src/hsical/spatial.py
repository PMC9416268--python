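"""Pixel-pitch, scanning-speed and resolving-power calibration.

Printed bar targets give the length scale: bar-edge crossings are localized
to sub-pixel precision (linear interpolation of the 50%-amplitude crossing,
amplitude bounded by the 5th/95th percentiles so the estimate is invariant
to global intensity scaling and to contrast inversion), the mean edge
spacing gives the period in pixels, and the known line frequency converts it
to mm/px.  Resolving power uses USAF1951 three-bar elements and a Michelson
contrast criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube import HyperCube, ReflectanceCube, extract_band
from .errors import InsufficientDataError
from .scenes import feature_size, usaf_frequency  # re-exported, defined with the targets

__all__ = [
    "usaf_frequency", "feature_size", "estimate_pixel_pitch",
    "pitch_from_span", "edge_positions", "resolving_power", "scan_aspect",
    "SpatialCalibration", "ElementContrast",
]


@dataclass
class SpatialCalibration:
    """Bundle of spatial-calibration results for one lens configuration."""

    pitch_mm_slit: float | None = None
    pitch_mm_scan: float | None = None
    elongation_percent: float | None = None
    speed_correction: float | None = None
    resolving: dict = field(default_factory=dict)  # axis -> (group, element, lp/mm)

    def to_dict(self) -> dict:
        return {
            "pitch_mm_slit": self.pitch_mm_slit,
            "pitch_mm_scan": self.pitch_mm_scan,
            "pitch_mm_slit_2dp": None if self.pitch_mm_slit is None
            else round(self.pitch_mm_slit, 2),
            "pitch_mm_scan_2dp": None if self.pitch_mm_scan is None
            else round(self.pitch_mm_scan, 2),
            "elongation_percent": self.elongation_percent,
            "speed_correction": self.speed_correction,
            "resolving": self.resolving,
        }


def edge_positions(profile: np.ndarray) -> np.ndarray:
    """Sub-pixel 50%-crossing positions of a bar-target intensity profile.

    Amplitude bounds come from the 5th/95th percentiles; every crossing of
    the mid-level, rising or falling, is localized by linear interpolation.
    """
    profile = np.asarray(profile, dtype=float)
    lo, hi = np.percentile(profile, [5, 95])
    if hi <= lo:
        return np.array([])
    mid = 0.5 * (lo + hi)
    above = profile > mid
    idx = np.flatnonzero(above[1:] != above[:-1])
    frac = (mid - profile[idx]) / (profile[idx + 1] - profile[idx])
    return idx + frac


def estimate_pixel_pitch(
    grid_image: np.ndarray, known_frequency_lpmm: float, axis: str = "slit"
) -> float:
    """Object-plane pixel pitch (mm/px) from a Ronchi-grid image.

    ``grid_image`` is a 2-D (scan, slit) band image of a grid of known line
    frequency; the profile is averaged along the non-varying axis.  Needs at
    least 3 full periods (7 edges) along the requested axis.
    """
    grid_image = np.asarray(grid_image, dtype=float)
    if grid_image.ndim != 2:
        raise ValueError("grid_image must be 2-D (scan, slit)")
    if known_frequency_lpmm <= 0:
        raise ValueError("known frequency must be > 0")
    profile = grid_image.mean(axis=1) if axis == "scan" else grid_image.mean(axis=0)
    edges = edge_positions(profile)
    if len(edges) < 7:
        raise InsufficientDataError(
            f"only {max(len(edges) - 1, 0) / 2:.1f} periods visible along {axis}; "
            "need >= 3"
        )
    period_px = 2.0 * float(np.mean(np.diff(edges)))
    return (1.0 / known_frequency_lpmm) / period_px


def pitch_from_span(span_mm: float, span_px: float) -> float:
    """Direct pitch estimate from a known physical span covering N pixels."""
    if span_mm <= 0 or span_px <= 0:
        raise ValueError("span must be positive")
    return span_mm / span_px


@dataclass
class ElementContrast:
    group: int
    element: int
    freq_lpmm: float
    axis: str
    contrasts: list[float]      # Michelson contrast per bar gap

    @property
    def discernible(self) -> bool:
        return bool(self.contrasts) and min(self.contrasts) >= self._threshold

    _threshold: float = 0.1


def resolving_power(
    usaf_cube: HyperCube | ReflectanceCube,
    band_nm: float | None,
    axis: str,
    geometry: dict,
    *,
    contrast_threshold: float = 0.1,
) -> tuple[tuple[int, int, float] | None, list[ElementContrast]]:
    """Smallest discernible USAF element along ``axis`` at one band.

    For each rendered three-bar element, Michelson contrast
    ``(I_max - I_min)/(I_max + I_min)`` is computed on each inter-bar gap
    against its neighbouring bars; an element is discernible when every gap
    clears ``contrast_threshold``.  Returns the finest passing
    ``(group, element, lp/mm)`` (or ``None`` if nothing passes) plus the full
    per-element contrast table.  Slit- and scan-axis resolutions are
    evaluated independently since they differ on a push-broom system.
    """
    if band_nm is None or usaf_cube.wavelength_nm is None:
        image = np.asarray(usaf_cube.values).mean(axis=2)
    else:
        image = extract_band(usaf_cube, band_nm)
    table: list[ElementContrast] = []
    for el in geometry["elements"]:
        if el["axis"] != axis:
            continue
        p_lo, p_hi = el["perp_range_px"]
        p_lo, p_hi = int(np.floor(p_lo)) + 1, int(np.ceil(p_hi)) - 1
        if axis == "slit":
            if p_hi <= p_lo or p_hi > image.shape[0]:
                continue
            profile_src = image[p_lo:p_hi, :].mean(axis=0)
        else:
            if p_hi <= p_lo or p_hi > image.shape[1]:
                continue
            profile_src = image[:, p_lo:p_hi].mean(axis=1)
        bar_w_px = (el["gap_centers_px"][0] - el["bar_centers_px"][0])
        half = max(int(round(bar_w_px / 4)), 1)

        def _level(center: float, reduce) -> float | None:
            c = int(round(center))
            lo, hi = c - half, c + half + 1
            if lo < 0 or hi > len(profile_src):
                return None
            return float(reduce(profile_src[lo:hi]))

        bar_levels = [_level(c, np.min) for c in el["bar_centers_px"]]
        gap_levels = [_level(c, np.max) for c in el["gap_centers_px"]]
        if any(v is None for v in bar_levels + gap_levels):
            continue
        contrasts = []
        for g, gap in enumerate(gap_levels):
            for bar in (bar_levels[g], bar_levels[g + 1]):
                denom = gap + bar
                contrasts.append((gap - bar) / denom if denom > 0 else 0.0)
        ec = ElementContrast(
            el["group"], el["element"], el["freq_lpmm"], axis, contrasts
        )
        ec._threshold = contrast_threshold
        table.append(ec)
    passing = [ec for ec in table if ec.discernible]
    if not passing:
        return None, table
    best = max(passing, key=lambda ec: ec.freq_lpmm)
    return (best.group, best.element, best.freq_lpmm), table


def scan_aspect(
    grid_cube: HyperCube | ReflectanceCube, band_nm: float | None = None
) -> tuple[float, float]:
    """Scan-axis elongation (%) and corrective speed factor from a square grid.

    The grid period is measured independently along each axis from bar-edge
    spacings; elongation is ``(scan_period / slit_period - 1) * 100`` and the
    corrective factor ``slit_period / scan_period`` multiplies the stage
    speed to restore square pixels.
    """
    if band_nm is None or grid_cube.wavelength_nm is None:
        image = np.asarray(grid_cube.values).mean(axis=2)
    else:
        image = extract_band(grid_cube, band_nm)
    periods = {}
    for axis_name, profile in (
        ("scan", image.mean(axis=1)),
        ("slit", image.mean(axis=0)),
    ):
        edges = edge_positions(profile)
        if len(edges) < 7:
            raise InsufficientDataError(
                f"fewer than 3 grid periods along the {axis_name} axis"
            )
        # a square-grid profile alternates bright/dark with equal widths,
        # so consecutive edges are half a period apart
        periods[axis_name] = 2.0 * float(np.mean(np.diff(edges)))
    elongation = (periods["scan"] / periods["slit"] - 1.0) * 100.0
    correction = periods["slit"] / periods["scan"]
    return elongation, correction
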