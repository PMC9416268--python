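"""Cubic wavelength-dispersion model of the imaging spectrograph.

The mapping from the 0-based spectral pixel index ``x`` to wavelength is
approximated by a third-order expansion

    lambda(x) = a + b*x + c*x^2 + d*x^3

with ``a`` in nm, ``b`` in nm/px, ``c`` in nm/px^2 and ``d`` in nm/px^3.
The model must be strictly increasing over the detector's spectral extent;
this is checked numerically at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import WavelengthRangeError


@dataclass
class DispersionModel:
    """Cubic pixel-to-wavelength map with coefficient uncertainties.

    ``covariance`` is the 4x4 covariance matrix of ``(a, b, c, d)`` from the
    calibration fit (zeros for an exactly known model).  The pixel convention
    is 0-based; ``n_spectral`` is the detector extent over which monotonicity
    is enforced.
    """

    a: float
    b: float
    c: float = 0.0
    d: float = 0.0
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    n_spectral: int = 2048

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (4, 4):
            raise ValueError("covariance must be 4x4")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        if eigvals.min() < -1e-10 * max(1.0, abs(eigvals).max()):
            raise ValueError("covariance must be positive semi-definite")
        x = np.linspace(0, self.n_spectral - 1, 4096)
        if np.any(self.derivative(x) <= 0):
            raise ValueError(
                "dispersion must be strictly increasing over the spectral extent"
            )

    # -- evaluation ------------------------------------------------------
    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d])

    def __call__(self, x):
        return self.wavelength_of_pixel(x)

    def wavelength_of_pixel(self, x):
        """Evaluate lambda(x) for fractional spectral pixel(s) ``x``."""
        x = np.asarray(x, dtype=float)
        out = self.a + x * (self.b + x * (self.c + x * self.d))
        return float(out) if out.ndim == 0 else out

    def derivative(self, x):
        """Local dispersion d(lambda)/dx = b + 2cx + 3dx^2 in nm/px."""
        x = np.asarray(x, dtype=float)
        out = self.b + x * (2 * self.c + x * (3 * self.d))
        return float(out) if out.ndim == 0 else out

    def pixel_of_wavelength(self, lam):
        """Numeric inverse of :meth:`wavelength_of_pixel`.

        Accurate to better than 1e-9 nm in the round trip.  Raises
        :class:`WavelengthRangeError` for wavelengths outside the range
        covered by pixels [-1, n_spectral].
        """
        scalar = np.isscalar(lam)
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        x_lo, x_hi = -1.0, float(self.n_spectral)
        lo, hi = self.wavelength_of_pixel(x_lo), self.wavelength_of_pixel(x_hi)
        out = np.empty_like(lam)
        for i, w in enumerate(lam):
            if not (lo <= w <= hi):
                raise WavelengthRangeError(
                    f"{w} nm outside calibrated range [{lo:.2f}, {hi:.2f}] nm"
                )
            out[i] = brentq(
                lambda x: self.wavelength_of_pixel(x) - w, x_lo, x_hi,
                xtol=1e-12, rtol=8.9e-16,
            )
        return float(out[0]) if scalar else out

    @property
    def coefficient_errors(self) -> np.ndarray:
        """1-sigma uncertainties of (a, b, c, d)."""
        return np.sqrt(np.diag(self.covariance))

    @classmethod
    def default_vis_nir(cls, n_spectral: int = 2048) -> "DispersionModel":
        """Typical VIS-NIR push-broom dispersion: ~338-1027 nm over 2048 px."""
        return cls(a=337.7, b=0.306, c=2.6e-5, d=-5.4e-9, n_spectral=n_spectral)

    @classmethod
    def identity(cls, n_spectral: int = 2048) -> "DispersionModel":
        """lambda(x) = x; convenient for unit tests."""
        return cls(a=0.0, b=1.0, n_spectral=n_spectral)

    def wavelength_axis(self) -> np.ndarray:
        """Wavelength of every detector spectral pixel."""
        return self.wavelength_of_pixel(np.arange(self.n_spectral))


def wavelength_of_pixel(model: DispersionModel, x):
    """Functional alias for :meth:`DispersionModel.wavelength_of_pixel`."""
    return model.wavelength_of_pixel(x)


def pixel_of_wavelength(model: DispersionModel, lam):
    """Functional alias for :meth:`DispersionModel.pixel_of_wavelength`."""
    return model.pixel_of_wavelength(lam)
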