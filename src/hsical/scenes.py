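"""Synthetic calibration targets and samples rendered on the object plane.

Targets mirror the printed standards used to calibrate a push-broom system:
Ronchi rulings (equal-width bright/dark bars, frequency ``1/(2w)`` lp/mm),
USAF1951 three-bar elements (frequency ``2^(group + (element-1)/6)`` lp/mm),
square grids for scanning-speed verification, plus uniform slabs and simple
two-region samples for verification work.

Rendering is area-averaged: each object-plane pixel is supersampled and
region membership averaged into fractional weights, so region boundaries are
band-limited the way a printed edge imaged onto a detector is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

Spectrum = float | tuple | Callable[[np.ndarray], np.ndarray]


def as_spectrum(spec: Spectrum) -> Callable[[np.ndarray], np.ndarray]:
    """Coerce a reflectance spec (scalar, (lams, values) pair, callable)."""
    if callable(spec):
        return spec
    if isinstance(spec, tuple):
        lams, values = np.asarray(spec[0], float), np.asarray(spec[1], float)
        return lambda lam: np.interp(np.asarray(lam, float), lams, values)
    value = float(spec)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"flat reflectance {value} outside [0, 1]")
    return lambda lam: np.full_like(np.asarray(lam, float), value)


def usaf_frequency(group: int, element: int) -> float:
    """Spatial frequency of a USAF1951 element: ``2^(group + (element-1)/6)`` lp/mm."""
    if not (1 <= element <= 6):
        raise ValueError(f"USAF element must be in 1..6; got {element}")
    return float(2.0 ** (group + (element - 1) / 6.0))


def feature_size(frequency_lpmm: float) -> float:
    """Bar width in mm for a bar-target frequency: ``w = 1/(2f)``."""
    if frequency_lpmm <= 0:
        raise ValueError("spatial frequency must be > 0")
    return 1.0 / (2.0 * frequency_lpmm)


@dataclass
class SceneSpec:
    """Declarative description of a target on the object plane.

    Use the class-method constructors; ``params`` holds kind-specific
    geometry in mm and ``regions`` maps region names to reflectance spectra
    (dimensionless, in [0, 1]).
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    regions: dict[str, Spectrum] = field(default_factory=dict)

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(cls, reflectance: Spectrum = 0.95) -> "SceneSpec":
        return cls("uniform", {}, {"field": reflectance})

    @classmethod
    def ronchi(
        cls,
        frequency_lpmm: float,
        axis: str = "slit",
        bright: Spectrum = 0.9,
        dark: Spectrum = 0.05,
    ) -> "SceneSpec":
        if frequency_lpmm <= 0:
            raise ValueError("Ronchi frequency must be > 0")
        _check_axis(axis)
        return cls(
            "ronchi",
            {"frequency_lpmm": float(frequency_lpmm), "axis": axis},
            {"bright": bright, "dark": dark},
        )

    @classmethod
    def square_grid(
        cls,
        period_mm: float,
        bright: Spectrum = 0.9,
        dark: Spectrum = 0.05,
        offset_mm: float = 0.0,
    ) -> "SceneSpec":
        if period_mm <= 0:
            raise ValueError("grid period must be > 0")
        return cls(
            "square_grid",
            {"period_mm": float(period_mm), "offset_mm": float(offset_mm)},
            {"bright": bright, "dark": dark},
        )

    @classmethod
    def usaf1951(
        cls,
        elements: list[tuple[int, int]],
        bright: Spectrum = 0.9,
        dark: Spectrum = 0.05,
        margin_mm: float = 1.0,
    ) -> "SceneSpec":
        if not elements:
            raise ValueError("need at least one (group, element) pair")
        for g, e in elements:
            usaf_frequency(g, e)  # validates
        return cls(
            "usaf1951",
            {"elements": [(int(g), int(e)) for g, e in elements],
             "margin_mm": float(margin_mm)},
            {"bright": bright, "dark": dark},
        )

    @classmethod
    def two_region(
        cls, left: Spectrum, right: Spectrum, axis: str = "slit"
    ) -> "SceneSpec":
        _check_axis(axis)
        return cls("two_region_sample", {"axis": axis}, {"left": left, "right": right})

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        regions = {}
        for name, spec in self.regions.items():
            if callable(spec):
                regions[name] = "custom"
            elif isinstance(spec, tuple):
                regions[name] = {
                    "wavelength_nm": np.asarray(spec[0]).tolist(),
                    "reflectance": np.asarray(spec[1]).tolist(),
                }
            else:
                regions[name] = float(spec)
        params = {
            k: (list(map(list, v)) if k == "elements" else v)
            for k, v in self.params.items()
        }
        return {"kind": self.kind, "params": params, "regions": regions}

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        regions: dict[str, Spectrum] = {}
        for name, spec in d["regions"].items():
            if spec == "custom":
                raise ValueError("cannot rebuild a scene with callable spectra")
            if isinstance(spec, dict):
                regions[name] = (spec["wavelength_nm"], spec["reflectance"])
            else:
                regions[name] = float(spec)
        params = dict(d["params"])
        if "elements" in params:
            params["elements"] = [tuple(p) for p in params["elements"]]
        return cls(d["kind"], params, regions)


def _check_axis(axis: str) -> None:
    if axis not in ("slit", "scan"):
        raise ValueError(f"axis must be 'slit' or 'scan'; got {axis!r}")


@dataclass
class RenderedScene:
    """Fractional region-membership weights plus geometry ground truth.

    ``weights`` has shape ``(n_regions, n_scan, n_slit)`` and sums to 1 over
    regions at every pixel; ``region_names`` orders the first axis.
    ``geometry`` records the rendered feature positions in pixels (periods,
    USAF bar/gap centers) for use as estimator ground truth.
    """

    weights: np.ndarray
    region_names: list[str]
    spectra: list[Callable[[np.ndarray], np.ndarray]]
    geometry: dict[str, Any]

    def reflectance_profiles(self, lam_nm: np.ndarray) -> np.ndarray:
        """Per-region reflectance evaluated on ``lam_nm``: shape (R, K)."""
        lam_nm = np.asarray(lam_nm, dtype=float)
        return np.stack([s(lam_nm) for s in self.spectra])

    def reflectance_map(self, lam: float) -> np.ndarray:
        """(n_scan, n_slit) reflectance at one wavelength."""
        rho = self.reflectance_profiles(np.atleast_1d(lam))[:, 0]
        return np.tensordot(rho, self.weights, axes=(0, 0))


def render_scene(
    scene: SceneSpec,
    pitch_mm: float,
    n_scan: int,
    n_slit: int,
    *,
    scan_step_mm: float | None = None,
    supersample: int = 4,
) -> RenderedScene:
    """Rasterize a scene onto the (scan, slit) object-plane pixel grid.

    ``pitch_mm`` is the object-plane size of one slit pixel; ``scan_step_mm``
    is the object-plane advance per scan line (defaults to ``pitch_mm``; a
    mismatch models an uncalibrated scanning speed).
    """
    if pitch_mm <= 0:
        raise ValueError("pixel pitch must be > 0")
    scan_step_mm = pitch_mm if scan_step_mm is None else float(scan_step_mm)
    ss = int(supersample)
    sub = (np.arange(ss) + 0.5) / ss
    u = (np.arange(n_scan)[:, None] + sub[None, :]).reshape(-1) * scan_step_mm
    v = (np.arange(n_slit)[:, None] + sub[None, :]).reshape(-1) * pitch_mm
    uu, vv = np.meshgrid(u, v, indexing="ij")  # (scan_ss, slit_ss), mm

    names = list(scene.regions)
    idx, geometry = _region_index(scene, uu, vv, pitch_mm, scan_step_mm)
    n_regions = len(names)
    weights = np.empty((n_regions, n_scan, n_slit))
    for r in range(n_regions):
        member = (idx == r).astype(float)
        weights[r] = member.reshape(n_scan, ss, n_slit, ss).mean(axis=(1, 3))
    spectra = [as_spectrum(scene.regions[name]) for name in names]
    return RenderedScene(weights, names, spectra, geometry)


def _region_index(scene, uu, vv, pitch_mm, scan_step_mm):
    kind = scene.kind
    if kind == "uniform":
        return np.zeros_like(uu, dtype=int), {}
    if kind == "ronchi":
        f = scene.params["frequency_lpmm"]
        w = feature_size(f)
        coord = vv if scene.params["axis"] == "slit" else uu
        idx = (np.floor(coord / w).astype(int)) % 2  # 0=bright, 1=dark
        step = pitch_mm if scene.params["axis"] == "slit" else scan_step_mm
        return idx, {"period_px": 2 * w / step, "bar_width_mm": w}
    if kind == "square_grid":
        p = scene.params["period_mm"]
        off = scene.params.get("offset_mm", 0.0)
        bright = (((uu - off) % p) < p / 2) & (((vv - off) % p) < p / 2)
        idx = np.where(bright, 0, 1)
        return idx, {
            "period_px_scan": p / scan_step_mm,
            "period_px_slit": p / pitch_mm,
        }
    if kind == "two_region_sample":
        coord = vv if scene.params["axis"] == "slit" else uu
        half = coord.max() / 2
        idx = np.where(coord < half, 0, 1)
        return idx, {"split_mm": half}
    if kind == "usaf1951":
        return _render_usaf(scene, uu, vv, pitch_mm, scan_step_mm)
    raise ValueError(f"unknown scene kind {scene.kind!r}")


def _render_usaf(scene, uu, vv, pitch_mm, scan_step_mm):
    """Lay USAF elements out as rows along the scan axis.

    Each element renders its three-bar pattern twice: once with bars varying
    along the slit axis and once varying along the scan axis.  Geometry
    records bar/gap center pixels per (group, element, axis).
    """
    margin = scene.params["margin_mm"]
    idx = np.zeros_like(uu, dtype=int)
    elements_geom = []
    u0 = margin
    for group, element in scene.params["elements"]:
        f = usaf_frequency(group, element)
        w = feature_size(f)
        length = 5.0 * w
        # slit-varying bars: rectangles spanning [u0, u0+length] in scan
        v_start = margin
        bar_v = [v_start + (2 * k) * w for k in range(3)]
        for bv in bar_v:
            sel = (uu >= u0) & (uu < u0 + length) & (vv >= bv) & (vv < bv + w)
            idx[sel] = 1
        elements_geom.append({
            "group": group, "element": element, "freq_lpmm": f, "axis": "slit",
            "bar_centers_px": [(bv + w / 2) / pitch_mm for bv in bar_v],
            "gap_centers_px": [(bv + 1.5 * w) / pitch_mm for bv in bar_v[:2]],
            "perp_range_px": [u0 / scan_step_mm, (u0 + length) / scan_step_mm],
        })
        # scan-varying bars: offset along slit past the first pattern
        v2 = v_start + length + 2.0 * w
        bar_u = [u0 + (2 * k) * w for k in range(3)]
        for bu in bar_u:
            sel = (vv >= v2) & (vv < v2 + length) & (uu >= bu) & (uu < bu + w)
            idx[sel] = 1
        elements_geom.append({
            "group": group, "element": element, "freq_lpmm": f, "axis": "scan",
            "bar_centers_px": [(bu + w / 2) / scan_step_mm for bu in bar_u],
            "gap_centers_px": [(bu + 1.5 * w) / scan_step_mm for bu in bar_u[:2]],
            "perp_range_px": [v2 / pitch_mm, (v2 + length) / pitch_mm],
        })
        u0 += length + 3.0 * w
    return idx, {"elements": elements_geom}
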