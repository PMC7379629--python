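"""Field geometry from 2D dose maps: centering, FWHM sizing, central ROI dose.

A small photon field is characterised by the full widths at half maximum
(FWHM) of its dose profiles at measurement depth, not by the collimator
setting: for sub-centimetre fields, source occlusion shrinks the output and
broadens the penumbra so that the dosimetric field differs from the nominal
one.  The equivalent square small field size is ``s_clin = sqrt(A * B)``
where ``A`` and ``B`` are the in-line and cross-line FWHM in cm.

Internally every length is millimetres; field sizes cross the API boundary
in centimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import BoundsError, DegenerateFieldError

__all__ = [
    "DoseMap2D",
    "DoseProfile",
    "FieldSize",
    "fwhm",
    "locate_field_center",
    "equivalent_square",
    "central_roi_dose",
    "measure_field",
]

MM_PER_CM = 10.0


@dataclass(frozen=True)
class DoseMap2D:
    """Calibrated dose on a regular grid.

    Parameters
    ----------
    values
        Dose in Gy, shape ``(ny, nx)``; row index advances along +y.
    spacing_x, spacing_y
        Pixel pitch in mm.
    origin
        Physical (x, y) coordinate in mm of the centre of pixel
        ``(row=0, col=0)``.  By default the grid is placed so its geometric
        centre sits at (0, 0).
    """

    values: np.ndarray
    spacing_x: float
    spacing_y: float
    origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 3:
            raise ValueError("dose map must be a 2D grid of at least 3x3")
        if not (self.spacing_x > 0 and self.spacing_y > 0):
            raise ValueError("pixel spacing must be positive")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("doses must be finite and non-negative")
        object.__setattr__(self, "values", v)
        if self.origin is None:
            ny, nx = v.shape
            object.__setattr__(
                self,
                "origin",
                (-(nx - 1) * self.spacing_x / 2.0, -(ny - 1) * self.spacing_y / 2.0),
            )

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinates (mm) of pixel centres."""
        return self.origin[0] + self.spacing_x * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinates (mm) of pixel centres."""
        return self.origin[1] + self.spacing_y * np.arange(self.values.shape[0])

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(
            (self.y, self.x), self.values, method="linear", bounds_error=True
        )

    def profile_x(self, y0: float) -> "DoseProfile":
        """Cross-line profile along x through physical height ``y0`` (mm)."""
        itp = self.interpolator()
        xs = self.x
        try:
            vals = itp(np.column_stack([np.full_like(xs, y0), xs]))
        except ValueError as exc:
            raise BoundsError(f"profile line y={y0} mm outside map") from exc
        return DoseProfile(xs.copy(), vals)

    def profile_y(self, x0: float) -> "DoseProfile":
        """In-line profile along y through physical abscissa ``x0`` (mm)."""
        itp = self.interpolator()
        ys = self.y
        try:
            vals = itp(np.column_stack([ys, np.full_like(ys, x0)]))
        except ValueError as exc:
            raise BoundsError(f"profile line x={x0} mm outside map") from exc
        return DoseProfile(ys.copy(), vals)


@dataclass(frozen=True)
class DoseProfile:
    """One-dimensional dose profile on strictly increasing positions (mm)."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if p.shape != v.shape or p.ndim != 1:
            raise ValueError("positions and values must be 1D of equal length")
        if not np.all(np.diff(p) > 0):
            raise ValueError("positions must be strictly increasing")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FieldSize:
    """FWHM field dimensions A (in-line) and B (cross-line), cm."""

    A: float
    B: float
    s_clin: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.B > 0):
            raise ValueError("field dimensions must be positive")
        object.__setattr__(self, "s_clin", math.sqrt(self.A * self.B))


def _half_max_crossings(profile: DoseProfile) -> tuple[float, float]:
    """Positions (mm) of the two half-maximum crossings, by linear interpolation."""
    pos, val = profile.positions, profile.values
    imax = int(np.argmax(val))
    half = val[imax] / 2.0
    if val[imax] <= 0:
        raise DegenerateFieldError("profile has no positive maximum")

    def cross(lo_idx: np.ndarray) -> float:
        # lo_idx: indices i where the segment (i, i+1) brackets the half level
        i = int(lo_idx[-1]) if lo_idx.size else -1
        if i < 0:
            raise DegenerateFieldError("profile never falls below half maximum")
        x0, x1 = pos[i], pos[i + 1]
        v0, v1 = val[i], val[i + 1]
        return x0 + (half - v0) / (v1 - v0) * (x1 - x0)

    left_side = np.nonzero((val[:imax] < half) & (val[1 : imax + 1] >= half))[0]
    right = np.nonzero((val[imax:-1] >= half) & (val[imax + 1 :] < half))[0]
    if left_side.size == 0 or right.size == 0:
        raise DegenerateFieldError("profile never falls below half maximum")
    x_left = cross(left_side)
    # rightmost bracketing taken on the left flank, first one on the right flank
    i = imax + int(right[0])
    x0, x1 = pos[i], pos[i + 1]
    v0, v1 = val[i], val[i + 1]
    x_right = x0 + (half - v0) / (v1 - v0) * (x1 - x0)
    return x_left, x_right


def fwhm(profile: DoseProfile) -> float:
    """Full width at half maximum (mm) of a dose profile.

    The half level is half the profile maximum; each crossing is located by
    linear interpolation between the two bracketing samples.
    """
    x_left, x_right = _half_max_crossings(profile)
    return x_right - x_left


def locate_field_center(dose_map: DoseMap2D, tol: float = 0.01, max_iter: int = 20
                        ) -> tuple[float, float]:
    """Centre (x, y) in mm of the irradiated field.

    The centre is the fixed point of: extract the row and column profiles
    through the current estimate, find the half-maximum crossings, move the
    estimate to the midpoint of the crossings on each axis.  Iteration stops
    when the update falls below ``tol`` mm (default 0.01).
    """
    iy, ix = np.unravel_index(int(np.argmax(dose_map.values)), dose_map.values.shape)
    ny, nx = dose_map.values.shape
    if ix in (0, nx - 1) or iy in (0, ny - 1):
        raise DegenerateFieldError("dose maximum lies on the map boundary")
    cx = float(dose_map.x[ix])
    cy = float(dose_map.y[iy])
    for _ in range(max_iter):
        lx, rx = _half_max_crossings(dose_map.profile_x(cy))
        ly, ry = _half_max_crossings(dose_map.profile_y(cx))
        nx_c = 0.5 * (lx + rx)
        ny_c = 0.5 * (ly + ry)
        shift = math.hypot(nx_c - cx, ny_c - cy)
        cx, cy = nx_c, ny_c
        if shift < tol:
            break
    return cx, cy


def equivalent_square(A: float, B: float) -> float:
    """Equivalent square small field size ``sqrt(A*B)`` (cm in, cm out)."""
    if not (A > 0 and B > 0):
        raise ValueError("field widths must be positive")
    return math.sqrt(A * B)


def central_roi_dose(dose_map: DoseMap2D, center: tuple[float, float],
                     diameter: float = 0.5) -> tuple[float, float]:
    """Mean and SD of dose over a circular ROI (diameter in mm) at ``center``.

    Pixels count when their centres fall inside the circle.  When the pitch
    is too coarse for at least 4 pixels, the ROI is resampled bilinearly at
    0.05 mm pitch first.
    """
    cx, cy = center
    r = diameter / 2.0
    if (cx - r < dose_map.x[0] or cx + r > dose_map.x[-1]
            or cy - r < dose_map.y[0] or cy + r > dose_map.y[-1]):
        raise BoundsError("ROI extends beyond the dose map")
    xx, yy = np.meshgrid(dose_map.x, dose_map.y)
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if mask.sum() >= 4:
        sel = dose_map.values[mask]
    else:
        pitch = 0.05
        g = np.arange(-r, r + pitch / 2, pitch)
        gx, gy = np.meshgrid(cx + g, cy + g)
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
        itp = dose_map.interpolator()
        sel = itp(np.column_stack([gy[inside], gx[inside]]))
    return float(np.mean(sel)), float(np.std(sel))


def measure_field(dose_map: DoseMap2D, roi_diameter: float = 0.5
                  ) -> tuple[FieldSize, tuple[float, float], tuple[float, float]]:
    """Locate the field and return (FieldSize [cm], centre [mm], ROI (mean, SD)).

    Convenience wrapper running centre finding, FWHM sizing on the centred
    profiles, and the central ROI dose in one call.
    """
    cx, cy = locate_field_center(dose_map)
    B = fwhm(dose_map.profile_x(cy)) / MM_PER_CM  # cross-line
    A = fwhm(dose_map.profile_y(cx)) / MM_PER_CM  # in-line
    mean, sd = central_roi_dose(dose_map, (cx, cy), roi_diameter)
    return FieldSize(A=A, B=B), (cx, cy), (mean, sd)
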