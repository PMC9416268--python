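"""Hypercube data model and band-level operations.

A push-broom system records one spatial line and the full spectral axis per
frame; the second spatial axis is built by scanning.  The canonical in-memory
layout is a 3-D array indexed ``(scan_line, slit_pixel, spectral_pixel)``,
0-based on every axis.  An optional wavelength axis (nm per spectral pixel,
strictly increasing) attaches once the spectral calibration is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InsufficientDataError, WavelengthRangeError

logger = logging.getLogger(__name__)

#: scan-axis, slit-axis, spectral-axis indices of the canonical layout
SCAN_AXIS, SLIT_AXIS, SPECTRAL_AXIS = 0, 1, 2


def _validate_values(values: np.ndarray, *, allow_negative: bool = False) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(
            f"cube values must be 3-D (scan, slit, spectral); got shape {values.shape}"
        )
    if min(values.shape) < 1:
        raise ValueError(f"all cube extents must be >= 1; got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("cube values must be finite")
    if not allow_negative and values.min() < 0:
        raise ValueError("raw cube counts must be non-negative")
    return values


def _validate_wavelength(wavelength_nm, n_spectral: int):
    if wavelength_nm is None:
        return None
    wavelength_nm = np.asarray(wavelength_nm, dtype=np.float64)
    if wavelength_nm.shape != (n_spectral,):
        raise ValueError(
            f"wavelength axis length {wavelength_nm.shape} does not match "
            f"spectral extent {n_spectral}"
        )
    if not np.all(np.diff(wavelength_nm) > 0):
        raise ValueError("wavelength axis must be strictly increasing")
    return wavelength_nm


@dataclass
class HyperCube:
    """Raw detector counts indexed ``(scan_line, slit_pixel, spectral_pixel)``.

    Parameters
    ----------
    values
        Non-negative finite counts, shape ``(n_scan, n_slit, n_spectral)``.
    wavelength_nm
        Optional calibrated wavelength per spectral pixel, strictly increasing.
    meta
        Acquisition metadata.  Conventional keys: ``focal_length_mm``,
        ``exposure_ms``, ``binning``, ``pixel_pitch_um``, ``scan_speed_factor``.
    """

    values: np.ndarray
    wavelength_nm: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.values = _validate_values(self.values)
        self.wavelength_nm = _validate_wavelength(self.wavelength_nm, self.n_spectral)

    # -- shape accessors -------------------------------------------------
    @property
    def n_scan(self) -> int:
        return self.values.shape[SCAN_AXIS]

    @property
    def n_slit(self) -> int:
        return self.values.shape[SLIT_AXIS]

    @property
    def n_spectral(self) -> int:
        return self.values.shape[SPECTRAL_AXIS]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ReflectanceCube:
    """Dimensionless reflectance/transmittance cube with an invalid-pixel mask.

    Values are clipped to ``[0, clip_max]`` (default 1.5) rather than masked,
    so that specular outliers remain visible in maps; ``mask`` records pixels
    that were clipped or had a non-positive normalization denominator.
    """

    values: np.ndarray
    wavelength_nm: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)
    mask: np.ndarray | None = None
    clip_max: float = 1.5

    def __post_init__(self):
        self.values = _validate_values(self.values, allow_negative=True)
        self.wavelength_nm = _validate_wavelength(self.wavelength_nm, self.n_spectral)
        if self.values.min() < 0 or self.values.max() > self.clip_max + 1e-12:
            raise ValueError(f"reflectance values must lie in [0, {self.clip_max}]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    n_scan = HyperCube.n_scan
    n_slit = HyperCube.n_slit
    n_spectral = HyperCube.n_spectral
    shape = HyperCube.shape


def normalize(
    raw: HyperCube,
    white: HyperCube,
    dark: HyperCube | None = None,
    *,
    clip_max: float = 1.5,
) -> ReflectanceCube:
    """White-reference normalization ``R = (S - D) / (W - D)``.

    The white and dark stacks are averaged over their scan lines before use
    (a dark stack is optional; omitting it is equivalent to an all-zero dark).
    Pixels whose denominator ``W - D`` is non-positive are flagged in the
    returned cube's ``mask`` (for every scan line) and set to 0 rather than
    propagated as NaN; clipped pixels are flagged as well.
    """
    w_mean = white.values.mean(axis=SCAN_AXIS)
    if dark is not None:
        d_mean = dark.values.mean(axis=SCAN_AXIS)
    else:
        d_mean = np.zeros_like(w_mean)
    for name, frame in (("white", w_mean), ("dark", d_mean)):
        if frame.shape != raw.values.shape[1:]:
            raise ValueError(
                f"{name} cube slit/spectral extents {frame.shape} do not match "
                f"raw cube {raw.values.shape[1:]}"
            )
    denom = w_mean - d_mean
    bad = denom <= 0
    safe_denom = np.where(bad, 1.0, denom)
    refl = (raw.values - d_mean[None]) / safe_denom[None]
    mask = np.broadcast_to(bad[None], refl.shape).copy()
    refl = np.where(mask, 0.0, refl)
    clipped = (refl < 0) | (refl > clip_max)
    refl = np.clip(refl, 0.0, clip_max)
    return ReflectanceCube(
        values=refl,
        wavelength_nm=raw.wavelength_nm,
        meta=dict(raw.meta),
        mask=mask | clipped,
        clip_max=clip_max,
    )


def extract_band(cube: HyperCube | ReflectanceCube, wavelength: float) -> np.ndarray:
    """Return the 2-D (scan, slit) image of the band nearest ``wavelength``.

    Ties between two equidistant bands break toward the lower index.  Raises
    :class:`WavelengthRangeError` if the request falls outside the axis by
    more than half the local band spacing.
    """
    axis = cube.wavelength_nm
    if axis is None:
        raise WavelengthRangeError("cube has no wavelength axis")
    if len(axis) == 1:
        lo_margin = hi_margin = np.inf
    else:
        lo_margin = (axis[1] - axis[0]) / 2
        hi_margin = (axis[-1] - axis[-2]) / 2
    if wavelength < axis[0] - lo_margin or wavelength > axis[-1] + hi_margin:
        raise WavelengthRangeError(
            f"requested {wavelength} nm outside covered range "
            f"[{axis[0]:.2f}, {axis[-1]:.2f}] nm"
        )
    dist = np.abs(axis - wavelength)
    idx = int(np.flatnonzero(dist <= dist.min() + 1e-12)[0])
    return cube.values[:, :, idx]


def bin_spatial(cube: HyperCube, factor: int) -> HyperCube:
    """Average non-overlapping groups of ``factor`` slit pixels.

    Remainder slit rows (when the slit extent is not divisible by ``factor``)
    are dropped with a logged warning.  The effective binning factor is
    recorded in ``meta['binning']``.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"binning factor must be a positive integer; got {factor}")
    factor = int(factor)
    if factor == 1:
        return HyperCube(cube.values.copy(), cube.wavelength_nm, dict(cube.meta))
    n_keep = (cube.n_slit // factor) * factor
    if n_keep == 0:
        raise InsufficientDataError(
            f"slit extent {cube.n_slit} smaller than binning factor {factor}"
        )
    if n_keep != cube.n_slit:
        logger.warning(
            "bin_spatial: dropping %d trailing slit rows (extent %d not divisible by %d)",
            cube.n_slit - n_keep, cube.n_slit, factor,
        )
    v = cube.values[:, :n_keep, :]
    binned = v.reshape(cube.n_scan, n_keep // factor, factor, cube.n_spectral).mean(axis=2)
    meta = dict(cube.meta)
    meta["binning"] = int(meta.get("binning", 1)) * factor
    return HyperCube(binned, cube.wavelength_nm, meta)
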