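"""Detector-specific output correction factors and their analytic fit.

A solid-state detector's raw signal ratio M_clin/M_ref differs from the true
field output factor because of fluence perturbation and volume averaging.
The output correction factor

    k(S) = Omega(S) / (M_clin / M_ref)

converts the measured ratio into the output factor.  Discrete k values are
fitted by the sigmoidal-plus-linear form used for tabulated correction
factors in small-field dosimetry codes of practice:

    k(S) = (1 + d*exp(-(10-a)/b)) / (1 + d*exp(-(S-a)/b)) + c*(S - 10)

which is identically 1 at the 10 cm reference field.  Data below a minimum
field size (default 0.8 cm) are excluded from the fit — the functional form
does not follow measured correction factors down to 0.5 cm — but are kept
in the output, flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CoverageError, FitError
from .stats import combine_relative_sd

__all__ = [
    "SignalRatio",
    "CorrectionCurveParams",
    "output_correction_factor",
    "evaluate_k",
    "fit_correction_curve",
]

REFERENCE_FIELD_CM = 10.0
DEFAULT_MIN_FIELD_CM = 0.8


@dataclass(frozen=True)
class SignalRatio:
    """Mean clinical-to-reference signal ratio for one detector and field."""

    s_clin: float  # cm
    detector: str
    ratio: float
    sd: float = 0.0
    beam: str = ""

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("signal ratio must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class CorrectionCurveParams:
    """Coefficients (a, b, c, d) of the analytic correction-factor curve."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("scale b must be positive")


def output_correction_factor(omega: float, ratio: SignalRatio,
                             omega_sd: float = 0.0) -> tuple[float, float]:
    """k = Omega / signal ratio, with SD propagated in quadrature.

    Omega and the ratio come from different detectors and sessions, so
    their relative SDs combine as independent.
    """
    if not omega > 0:
        raise ValueError("omega must be positive")
    k = omega / ratio.ratio
    rel = combine_relative_sd([
        omega_sd / omega if omega_sd else 0.0,
        ratio.sd / ratio.ratio if ratio.sd else 0.0,
    ])
    return k, k * rel


def evaluate_k(params: CorrectionCurveParams, S):
    """Analytic correction factor k(S); exactly 1 at the 10 cm reference."""
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise ValueError("field size must be positive")
    a, b, c, d = params.a, params.b, params.c, params.d

    def sig(s):
        return 1.0 + d * np.exp(np.clip(-(s - a) / b, -700.0, 700.0))

    val = sig(REFERENCE_FIELD_CM) / sig(S) + c * (S - REFERENCE_FIELD_CM)
    return val if val.ndim else float(val)


def fit_correction_curve(points: pd.DataFrame,
                         min_field_cm: float = DEFAULT_MIN_FIELD_CM,
                         seed: int = 0, n_starts: int = 5,
                         fix_d: float | None = None
                         ) -> tuple[CorrectionCurveParams, pd.DataFrame]:
    """SD-weighted fit of the analytic k(S) curve.

    ``points`` needs columns ``s_clin``, ``k`` and optionally ``sd``.  Rows
    with ``s_clin < min_field_cm`` are excluded from the residuals and
    returned flagged (``used == False``).  ``fix_d`` freezes the d
    coefficient instead of fitting it.

    Returns the fitted parameters and the annotated point table.
    """
    pts = points.copy()
    if "sd" not in pts:
        pts["sd"] = 0.0
    pts["used"] = pts["s_clin"] >= min_field_cm
    fit_pts = pts[pts["used"]]
    if len(fit_pts) < 4:
        raise CoverageError(
            f"need >= 4 points with s_clin >= {min_field_cm} cm")
    S = fit_pts["s_clin"].to_numpy(dtype=float)
    k = fit_pts["k"].to_numpy(dtype=float)
    sd = fit_pts["sd"].to_numpy(dtype=float)
    pos = sd[sd > 0]
    fill = np.median(pos) if pos.size else 1.0
    w = 1.0 / np.where(sd > 0, sd, fill)

    free_d = fix_d is None

    def unpack(p):
        a, logb, c = p[0], p[1], p[2]
        d = p[3] if free_d else fix_d
        return CorrectionCurveParams(a=a, b=math.exp(logb), c=c, d=d)

    def resid(p):
        return (evaluate_k(unpack(p), S) - k) * w

    # the curve's deviation from 1 at small S sets the sign/size of d
    dev = float(k[np.argmin(S)]) - 1.0
    x0_base = [0.3, math.log(0.5), 0.0, -dev]
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        if i == 0:
            x0 = list(x0_base)
        else:
            x0 = [rng.uniform(-0.5, 1.5), math.log(rng.uniform(0.2, 2.0)),
                  rng.normal(0.0, 1e-3), -dev * rng.uniform(0.2, 5.0)]
        if not free_d:
            x0 = x0[:3]
        try:
            sol = least_squares(resid, x0=np.asarray(x0, dtype=float),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                max_nfev=4000)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("correction-curve fit did not converge from any start")
    return unpack(best.x), pts
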