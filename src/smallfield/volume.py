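"""Volume-averaging corrections from bivariate Gaussian fits of the central dose.

A detector of finite lateral extent reads the dose averaged over its active
area.  On the non-flat top of a small field the average falls below the
central-axis dose, so the reading must be multiplied by a volume-averaging
correction factor ``k_vol >= 1``.  Here the central 3 mm x 3 mm of the
film-measured dose distribution is fitted to

    f(x, y) = a * exp(-0.5 * ((x/b)^2 + (y/c)^2))

and ``k_vol`` for a detector whose circular active area (radius ``r``) is
replaced by the equal-area square of side ``d = r*sqrt(pi)`` is the ratio of
the central dose integrated over that square to the Gaussian integral:

    k_vol = d^2 / (2*pi*b*c * erf(d/(2*sqrt(2)*b)) * erf(d/(2*sqrt(2)*c)))

The peak amplitude ``a`` cancels.  All lengths here are millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.optimize import least_squares
from scipy.special import erf

from .errors import BoundsError, FitError
from .geometry import DoseMap2D

__all__ = [
    "BivariateGaussianFit",
    "DetectorGeometry",
    "VolumeAveragingFactor",
    "fit_central_gaussian",
    "equivalent_detector_side",
    "kvol_closed_form",
    "kvol_numeric",
]

#: k_vol corrections smaller than this (k_vol - 1) are conventionally skipped
DEFAULT_KVOL_THRESHOLD = 1e-3

_SCALE_BOUND_MM = 100.0  # a fitted Gaussian scale beyond this means "no peak"


@dataclass(frozen=True)
class BivariateGaussianFit:
    """Parameters (a, b, c) of the central bivariate Gaussian, plus fit quality."""

    a: float
    b: float
    c: float
    residual_rms: float = 0.0
    field_label: str = ""
    energy_label: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("Gaussian amplitude and scales must be positive")

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-0.5 * ((np.asarray(x) / self.b) ** 2
                                       + (np.asarray(y) / self.c) ** 2))


@dataclass(frozen=True)
class DetectorGeometry:
    """Lateral active-area geometry of a point detector.

    ``dimension`` is the radius for circular detectors and the side for
    square ones (mm).  ``equivalent_side_d`` is the side of the equal-area
    square, ``r*sqrt(pi)`` for circles.
    """

    name: str
    shape: str  # "circular" | "square"
    dimension: float
    equivalent_side_d: float = field(init=False)

    def __post_init__(self) -> None:
        if self.shape not in ("circular", "square"):
            raise ValueError(f"unknown detector shape {self.shape!r}")
        if not self.dimension > 0:
            raise ValueError("detector dimension must be positive")
        d = self.dimension * math.sqrt(math.pi) if self.shape == "circular" \
            else self.dimension
        object.__setattr__(self, "equivalent_side_d", d)


@dataclass(frozen=True)
class VolumeAveragingFactor:
    """A computed k_vol with its provenance labels."""

    k_vol: float
    detector: str
    s_clin: float  # cm
    energy_label: str = ""

    def __post_init__(self) -> None:
        if self.k_vol < 1.0 - 1e-9:
            raise ValueError("k_vol must be >= 1")


def equivalent_detector_side(geom: DetectorGeometry) -> float:
    """Side d (mm) of the square of equal area to the detector footprint."""
    return geom.equivalent_side_d


def fit_central_gaussian(dose_map: DoseMap2D, center: tuple[float, float],
                         half_extent: float = 1.5,
                         field_label: str = "", energy_label: str = ""
                         ) -> BivariateGaussianFit:
    """Least-squares bivariate Gaussian fit over the central square region.

    Only grid points with ``|x - cx| <= half_extent`` and
    ``|y - cy| <= half_extent`` (mm) enter the fit.  Three starting points
    are tried; scales are reported as absolute values.
    """
    cx, cy = center
    if (cx - half_extent < dose_map.x[0] or cx + half_extent > dose_map.x[-1]
            or cy - half_extent < dose_map.y[0] or cy + half_extent > dose_map.y[-1]):
        raise BoundsError("central fit region extends beyond the dose map")
    xx, yy = np.meshgrid(dose_map.x - cx, dose_map.y - cy)
    mask = (np.abs(xx) <= half_extent) & (np.abs(yy) <= half_extent)
    x, y, z = xx[mask], yy[mask], dose_map.values[mask]
    if x.size < 6:
        raise FitError("too few grid points in the central region")
    a0 = float(z.max())
    if a0 <= 0:
        raise FitError("no positive dose in the central region")
    s0 = max(half_extent / 1.177, 0.3)  # region half-width as a FWHM/2.355 proxy

    def resid(p):
        a, b, c = p
        return a * np.exp(-0.5 * ((x / b) ** 2 + (y / c) ** 2)) - z

    best = None
    for scale in (s0, 3.0 * s0, 0.5 * s0):
        try:
            sol = least_squares(
                resid, x0=[a0, scale, scale],
                bounds=([1e-12, 1e-3, 1e-3],
                        [np.inf, _SCALE_BOUND_MM, _SCALE_BOUND_MM]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("bivariate Gaussian fit did not converge")
    a, b, c = best.x
    b, c = abs(b), abs(c)
    if b >= _SCALE_BOUND_MM * 0.999 or c >= _SCALE_BOUND_MM * 0.999:
        raise FitError("fitted Gaussian scales diverged (flat dose region)")
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return BivariateGaussianFit(a=float(a), b=float(b), c=float(c),
                                residual_rms=rms, field_label=field_label,
                                energy_label=energy_label)


def kvol_closed_form(d: float, fit: BivariateGaussianFit) -> float:
    """Closed-form volume-averaging factor for equivalent square side ``d`` (mm).

    The amplitude cancels; only the Gaussian scales b and c matter.  The
    result is clipped to 1 only against sub-1e-9 numerical undershoot.
    """
    if not d > 0:
        raise ValueError("equivalent square side d must be positive")
    b, c = fit.b, fit.c
    s = math.sqrt(2.0)
    val = d**2 / (2.0 * math.pi * b * c
                  * erf(d / (2.0 * s * b)) * erf(d / (2.0 * s * c)))
    if 1.0 - 1e-9 < val < 1.0:
        val = 1.0
    return val


def kvol_numeric(d: float, fit: BivariateGaussianFit, tol: float = 1e-12) -> float:
    """Quadrature evaluation of k_vol: d^2 * a over the integral of the fitted
    Gaussian on the centred d x d square.  Cross-check for the closed form."""
    if not d > 0:
        raise ValueError("equivalent square side d must be positive")
    h = d / 2.0

    def integrand(y, x):
        return fit.a * math.exp(-0.5 * ((x / fit.b) ** 2 + (y / fit.c) ** 2))

    area, err = integrate.dblquad(integrand, -h, h, -h, h,
                                  epsabs=tol, epsrel=tol)
    val = fit.a * d**2 / area
    if 1.0 - 1e-9 < val < 1.0:
        val = 1.0
    return val
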