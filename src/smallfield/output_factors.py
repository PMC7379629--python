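"""Field output factor determination: signal correction, joint curve fitting,
and tabulation with bootstrap uncertainties.

The field output factor Omega(S) is the dose ratio between a clinical field
of equivalent square size S and the 10 cm x 10 cm reference field.  Signals
from the two reference detectors (film and scintillator), corrected for
volume averaging and cross-normalized, are fitted jointly by the
Sauer-Wilbert saturation model

    Omega(S) = P_inf * S^n / (l^n + S^n) + S_inf * (1 - exp(-b*S))

under a Gaussian likelihood with known per-point standard deviations, which
is maximised by SD-weighted least squares.  The fitted curve is normalized
to 1 at S = 10 cm after the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import CoverageError, FitError

__all__ = [
    "SauerWilbertParams",
    "CorrectedReading",
    "OutputFactorCurve",
    "correct_film_reading",
    "sauer_wilbert",
    "evaluate_output_factor",
    "fit_output_factor_curve",
    "tabulate_output_factors",
]

NORMALIZATION_FIELD_CM = 10.0

#: fit bounds: (P_inf, n, l, S_inf, b); S_inf may go slightly negative and
#: large, admitting near-degenerate solutions where S_inf and b trade off
_LOWER = np.array([1e-9, 1e-9, 1e-9, -1.0 + 1e-9, 1e-9])
_UPPER = np.array([np.inf, np.inf, np.inf, 10.0, np.inf])


@dataclass(frozen=True)
class SauerWilbertParams:
    """Parameters of the saturation model; l and b are per-cm scales."""

    p_inf: float
    n: float
    l: float
    s_inf: float
    b: float

    def __post_init__(self) -> None:
        if not (self.p_inf > 0 and self.n > 0 and self.l > 0 and self.b > 0):
            raise ValueError("p_inf, n, l, b must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_inf, self.n, self.l, self.s_inf, self.b])


@dataclass(frozen=True)
class CorrectedReading:
    """A volume-averaging-corrected relative signal at one field size."""

    s_clin: float  # cm
    detector: str  # "EBT3" | "W1"
    value: float
    sd: float
    beam: str = ""

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("corrected signal must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def correct_film_reading(signal: float, kvol_ebt3: float) -> float:
    """Film signal corrected for volume averaging (simple product)."""
    if not (signal > 0 and kvol_ebt3 > 0):
        raise ValueError("signal and k_vol must be positive")
    return signal * kvol_ebt3


def sauer_wilbert(S, params: SauerWilbertParams):
    """Unnormalized Omega(S); S in cm, scalar or array.

    The power term is computed in log space and overflow-guarded so very
    large n * ln(S) cannot produce non-finite intermediates.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise ValueError("field size must be positive")
    logS = np.log(S)
    logl = np.log(params.l)
    # S^n/(l^n+S^n) = 1/(1+exp(n*(log l - log S))): bounded in (0,1)
    expo = np.clip(params.n * (logl - logS), -700.0, 700.0)
    sat = 1.0 / (1.0 + np.exp(expo))
    val = params.p_inf * sat + params.s_inf * (1.0 - np.exp(-params.b * S))
    return val if val.ndim else float(val)


@dataclass(frozen=True)
class OutputFactorCurve:
    """A fitted output-factor curve with its bootstrap parameter ensemble."""

    params: SauerWilbertParams
    beam: str = ""
    ensemble: tuple[SauerWilbertParams, ...] = ()
    normalization: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "normalization",
            sauer_wilbert(NORMALIZATION_FIELD_CM, self.params))

    def __call__(self, S):
        return evaluate_output_factor(self, S)

    def sd(self, S) -> np.ndarray:
        """1-SD of the normalized curve at S from the bootstrap ensemble."""
        if not self.ensemble:
            return np.zeros_like(np.asarray(S, dtype=float))
        draws = np.array([
            sauer_wilbert(S, p) / sauer_wilbert(NORMALIZATION_FIELD_CM, p)
            for p in self.ensemble
        ])
        return draws.std(axis=0, ddof=1)


def evaluate_output_factor(curve: OutputFactorCurve, S):
    """Normalized output factor Omega(S) / Omega(10 cm)."""
    return sauer_wilbert(S, curve.params) / curve.normalization


def _fit_once(S, val, w, x0):
    def resid(p):
        params = SauerWilbertParams(*p)
        return (sauer_wilbert(S, params) - val) * w

    return least_squares(resid, x0=np.clip(x0, _LOWER, _UPPER),
                         bounds=(_LOWER, _UPPER),
                         xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)


def fit_output_factor_curve(points: list[CorrectedReading], seed: int = 0,
                            n_starts: int = 5, n_bootstrap: int = 500,
                            beam: str = "") -> OutputFactorCurve:
    """Joint SD-weighted fit of the saturation model to both detectors' points.

    Film and scintillator points enter on an equal footing, each weighted by
    its own SD (points with sd == 0 get the median weight).  The optimiser
    is restarted from ``n_starts`` randomized initial points; the parameter
    uncertainty is a seeded parametric bootstrap of size ``n_bootstrap``.
    """
    if len(points) < 6:
        raise CoverageError("need at least 6 corrected readings")
    S = np.array([p.s_clin for p in points])
    val = np.array([p.value for p in points])
    sd = np.array([p.sd for p in points])
    uniq = np.unique(S)
    # the reference-field condition carries slack for FWHM measurement error
    if (uniq.size < 6 or uniq.min() >= 1.0
            or uniq.max() < 0.95 * NORMALIZATION_FIELD_CM):
        raise CoverageError(
            "fit needs >= 6 distinct field sizes spanning below 1 cm "
            "and reaching the 10 cm reference field")
    pos = sd[sd > 0]
    fill = np.median(pos) if pos.size else 1.0
    w = 1.0 / np.where(sd > 0, sd, fill)

    rng = np.random.default_rng(seed)
    top = float(val[np.argmax(S)])
    x0_base = np.array([0.75 * top, 2.0, 0.5, 0.3 * top, 0.15])
    best = None
    for k in range(n_starts):
        x0 = x0_base if k == 0 else x0_base * rng.uniform(0.4, 2.5, size=5)
        x0[3] = x0_base[3] if k == 0 else rng.uniform(-0.5, 2.0)
        try:
            sol = _fit_once(S, val, w, x0)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("output-factor fit did not converge from any start")
    params = SauerWilbertParams(*best.x)

    ensemble: list[SauerWilbertParams] = []
    model = sauer_wilbert(S, params)
    noise_sd = np.where(sd > 0, sd, 0.0)
    for _ in range(n_bootstrap):
        fake = model + rng.normal(0.0, 1.0, size=S.size) * noise_sd
        fake = np.maximum(fake, 1e-9)
        try:
            sol = _fit_once(S, fake, w, best.x)
        except Exception:
            continue
        if sol.success:
            ensemble.append(SauerWilbertParams(*sol.x))
    return OutputFactorCurve(params=params, beam=beam, ensemble=tuple(ensemble))


def tabulate_output_factors(curve: OutputFactorCurve,
                            s_clin: list[float],
                            nominal: list[float] | None = None) -> pd.DataFrame:
    """Discrete normalized output factors with bootstrap 1-SD per field size.

    Note the tabulated value at a measured size near (but not exactly) 10 cm
    differs slightly from 1, since normalization is pinned at exactly 10 cm.
    """
    s = np.asarray(s_clin, dtype=float)
    omega = np.atleast_1d(evaluate_output_factor(curve, s))
    sds = np.atleast_1d(curve.sd(s))
    out = pd.DataFrame({
        "nominal_field_cm": nominal if nominal is not None else s,
        "s_clin_cm": s,
        "omega": omega,
        "sd": sds,
    })
    exact = np.isclose(s, NORMALIZATION_FIELD_CM)
    out.loc[exact, "sd"] = 0.0
    return out
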