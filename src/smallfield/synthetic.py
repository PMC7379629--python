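"""Synthetic measurement campaigns with planted ground truth.

No public repository of raw small-field film scans and electrometer logs
exists, so the pipeline is validated against simulated campaigns in which
every quantity the analysis should recover is planted explicitly:

* 2D dose maps follow a separable rect (x) Gaussian-penumbra model,
  ``D(x, y) = D0 * g(x; w, sigma) * g(y; w, sigma)`` with

      g(u; w, sigma) = 0.5 * [erf((w/2 - u)/(sigma*sqrt(2)))
                              + erf((w/2 + u)/(sigma*sqrt(2)))]

  For ``w >> sigma`` the centre is flat; for ``w`` of a few sigma the peak
  is rounded and depressed, the surrogate of partial source occlusion, and
  the FWHM exceeds the collimator setting ``w`` just as measured
  equivalent squares exceed nominal sizes on real machines.

* detector readings are built from a planted output-factor curve
  Omega_true, the exact volume-averaging factor of the dose model for each
  detector footprint, and a planted perturbation curve p(S) per solid-state
  detector: ratio(S) = Omega_true(S) / (kvol_true(S) * p(S)).  The full
  pipeline should return Omega_true and k_true = kvol_true * p.

* scintillator channel pairs are constructed so that subtracting the
  planted Cerenkov light ratio times channel 2 recovers the intended
  signal exactly.

All randomness flows from a single integer seed through spawned generators,
so a campaign is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf

from . import beams
from .correction import CorrectionCurveParams, evaluate_k
from .errors import ConfigError
from .geometry import DoseMap2D
from .output_factors import SauerWilbertParams, sauer_wilbert
from .volume import DetectorGeometry

__all__ = [
    "SimulationConfig",
    "SyntheticCampaign",
    "field_profile",
    "analytic_fwhm",
    "model_kvol",
    "simulate_dose_map",
    "simulate_readings",
    "simulate_campaign",
]

#: default grid pitch, mm (150 dpi scanner resolution)
DEFAULT_PITCH_MM = 25.4 / 150.0

#: default relative 1-SD noise per detector class, matching the percent-level
#: repeatability of film, scintillator and diode charge readings
DEFAULT_NOISE = {"EBT3": 0.008, "W1": 0.005, "diode": 0.005}

#: planted Cerenkov light ratio used for synthetic two-channel data
DEFAULT_CLR = 0.95

#: planted scintillator-vs-film absolute scale (epsilon-bar ground truth)
DEFAULT_W1_SCALE = 12.5

_REFERENCE_DETECTORS = ("EBT3", "W1")


def field_profile(u, w_mm: float, sigma_mm: float):
    """1D collimated-field profile g(u; w, sigma), normalized to open beam."""
    s = sigma_mm * np.sqrt(2.0)
    u = np.asarray(u, dtype=float)
    val = 0.5 * (erf((w_mm / 2.0 - u) / s) + erf((w_mm / 2.0 + u) / s))
    return val if val.ndim else float(val)


def analytic_fwhm(w_mm: float, sigma_mm: float) -> float:
    """FWHM (mm) of the 1D field model, by root finding on the half level."""
    peak = field_profile(0.0, w_mm, sigma_mm)
    r = brentq(lambda u: field_profile(u, w_mm, sigma_mm) - peak / 2.0,
               0.0, w_mm / 2.0 + 8.0 * sigma_mm)
    return 2.0 * r


def model_kvol(geom: DetectorGeometry, w_mm: float, sigma_mm: float) -> float:
    """Exact volume-averaging factor of the separable dose model for a
    detector footprint (equal-area d x d square), with no Gaussian
    approximation: central dose over the mean dose on the square."""
    d = geom.equivalent_side_d
    h = d / 2.0
    num, _ = quad(lambda u: field_profile(u, w_mm, sigma_mm), -h, h,
                  epsabs=1e-13, epsrel=1e-13)
    g0 = field_profile(0.0, w_mm, sigma_mm)
    # separable model: 2D average factorises into the square of the 1D one
    return (g0 * d / num) ** 2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated campaign.

    Defaults reproduce the characterised beams: the truth curve and
    penumbra width come from the shipped per-beam reference data, the
    field list is the standard nine nominal sizes, and noise levels are
    the percent-level repeatabilities of each detector class.
    """

    linac: str = "Elekta Versa HD"
    beam: str = "6 MV WFF"
    seed: int = 0
    truth_curve: SauerWilbertParams | None = None
    penumbra_sigma_mm: float | None = None
    fields_cm: tuple[float, ...] = beams.NOMINAL_FIELDS_CM
    pitch_mm: float = DEFAULT_PITCH_MM
    noise: Mapping[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_NOISE))
    detector_perturbations: Mapping[str, CorrectionCurveParams] = dc_field(
        default_factory=dict)
    clr: float = DEFAULT_CLR
    w1_scale: float = DEFAULT_W1_SCALE
    n_repeats: int = 3
    peak_dose_gy: float = 2.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.noise.values()):
            raise ConfigError("noise SDs must be non-negative")
        if beams.REFERENCE_FIELD_CM not in self.fields_cm:
            raise ConfigError("field list must include the 10 cm reference field")

    @property
    def key(self) -> tuple[str, str]:
        return (self.linac, self.beam)

    def resolved_truth(self) -> SauerWilbertParams:
        if self.truth_curve is not None:
            return self.truth_curve
        try:
            return beams.REFERENCE_CURVES[self.key]
        except KeyError:
            raise ConfigError(f"no reference curve for beam {self.key}") from None

    def resolved_sigma(self) -> float:
        if self.penumbra_sigma_mm is not None:
            if not self.penumbra_sigma_mm > 0:
                raise ConfigError("penumbra sigma must be positive")
            return self.penumbra_sigma_mm
        try:
            return beams.DEFAULT_PENUMBRA_SIGMA_MM[self.key]
        except KeyError:
            raise ConfigError(f"no penumbra default for beam {self.key}") from None

    def noise_for(self, detector: str) -> float:
        if detector in self.noise:
            return float(self.noise[detector])
        return float(self.noise.get("diode", 0.0))


def simulate_dose_map(nominal_side_cm: float, penumbra_sigma_mm: float,
                      pitch_mm: float = DEFAULT_PITCH_MM,
                      peak_dose_gy: float = 2.0,
                      noise_rel: float = 0.0,
                      rng: np.random.Generator | None = None,
                      margin_sigmas: float = 8.0) -> DoseMap2D:
    """Simulated film dose map of one square field (separable erf model)."""
    if not (nominal_side_cm > 0 and penumbra_sigma_mm > 0):
        raise ConfigError("field size and penumbra sigma must be positive")
    w = nominal_side_cm * 10.0
    half = w / 2.0 + margin_sigmas * penumbra_sigma_mm
    n = int(np.ceil(half / pitch_mm))
    if n < 2:
        raise ConfigError("grid too small for the requested field")
    coords = pitch_mm * np.arange(-n, n + 1)
    g = field_profile(coords, w, penumbra_sigma_mm)
    dose = peak_dose_gy * np.outer(g, g) / field_profile(0.0, w, penumbra_sigma_mm) ** 2
    if noise_rel > 0:
        if rng is None:
            raise ConfigError("noisy maps need an explicit random generator")
        dose = dose * (1.0 + noise_rel * rng.standard_normal(dose.shape))
        dose = np.maximum(dose, 0.0)
    return DoseMap2D(values=dose, spacing_x=pitch_mm, spacing_y=pitch_mm)


def _planted_ratio(config: SimulationConfig, detector: str,
                   nominal_cm: float) -> float:
    """Noise-free M_clin/M_ref the detector should report for this field."""
    params = config.resolved_truth()
    sigma = config.resolved_sigma()
    s_meas = {
        f: analytic_fwhm(f * 10.0, sigma) / 10.0 for f in (nominal_cm,
                                                           beams.REFERENCE_FIELD_CM)
    }
    omega = (sauer_wilbert(s_meas[nominal_cm], params)
             / sauer_wilbert(s_meas[beams.REFERENCE_FIELD_CM], params))

    if detector == "EBT3":
        geom = beams.detector("EBT3 ROI")
    elif detector == "W1":
        geom = beams.detector("W1 PSD")
    else:
        geom = beams.detector(detector)
    kv_clin = model_kvol(geom, nominal_cm * 10.0, sigma)
    kv_ref = model_kvol(geom, beams.REFERENCE_FIELD_CM * 10.0, sigma)
    ratio = omega * kv_ref / kv_clin

    if detector not in _REFERENCE_DETECTORS:
        pert = config.detector_perturbations.get(detector)
        if pert is not None:
            s = analytic_fwhm(nominal_cm * 10.0, sigma) / 10.0
            ratio = ratio / evaluate_k(pert, s)
    return float(ratio)


def simulate_readings(config: SimulationConfig, detector: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Repeated readings for one detector across all configured fields.

    Reference-field readings are emitted twice (sessions ``pre`` and
    ``post``) to mirror the bracketing reference measurements of a real
    session; clinical fields get one session of ``n_repeats`` readings.
    The scintillator additionally gets a channel-2 (Cerenkov) reading
    constructed so the planted CLR recovers the intended signal.
    """
    known = {"EBT3", "W1"} | {g.name for g in beams.DETECTORS}
    if detector not in known:
        raise ConfigError(f"unknown detector {detector!r}")
    base = 1.0 if detector == "EBT3" else 20.0  # Gy-scale vs nC-scale
    scale = config.w1_scale if detector == "W1" else 1.0
    noise = config.noise_for(detector)
    energy, filt = config.beam.rsplit(" ", 1)
    rows = []
    for nominal in sorted(config.fields_cm):
        ratio = _planted_ratio(config, detector, nominal)
        sessions = (("pre", "post") if nominal == beams.REFERENCE_FIELD_CM
                    else ("clin",))
        for session in sessions:
            for rep in range(config.n_repeats):
                signal = base * scale * ratio * (
                    1.0 + noise * rng.standard_normal())
                row = {
                    "linac": config.linac, "energy": energy, "filter": filt,
                    "detector": detector, "nominal_field": nominal,
                    "session_position": session, "repeat_index": rep,
                    "ch1": signal,
                }
                if detector == "W1":
                    # fibre-length surrogate: more Cerenkov in larger fields
                    ch2 = 0.3 * base * scale * ratio * np.sqrt(nominal / 10.0)
                    row["ch1"] = signal + config.clr * ch2
                    row["ch2"] = ch2
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticCampaign:
    """One beam's simulated campaign: dose maps, readings, planted truth."""

    config: SimulationConfig
    dose_maps: dict[float, DoseMap2D]
    readings: pd.DataFrame
    truth: dict

    def readings_for(self, detector: str) -> pd.DataFrame:
        return self.readings[self.readings["detector"] == detector]


def simulate_campaign(config: SimulationConfig,
                      detectors: tuple[str, ...] = ("EBT3", "W1"),
                      map_noise: bool = True) -> SyntheticCampaign:
    """Simulate dose maps and reading tables for one beam.

    ``detectors`` lists the reading tables to generate ("EBT3", "W1" and/or
    any shipped solid-state detector name).  Film maps always carry the
    film-class noise unless ``map_noise`` is false.
    """
    root = np.random.SeedSequence(config.seed)
    map_seed, read_seed = root.spawn(2)
    sigma = config.resolved_sigma()
    params = config.resolved_truth()

    dose_maps: dict[float, DoseMap2D] = {}
    map_rngs = map_seed.spawn(len(config.fields_cm))
    film_noise = config.noise_for("EBT3") if map_noise else 0.0
    s_true: dict[float, float] = {}
    for nominal, seq in zip(sorted(config.fields_cm), map_rngs):
        fw = analytic_fwhm(nominal * 10.0, sigma)
        s_true[nominal] = fw / 10.0
        peak = config.peak_dose_gy  # each field delivered to ~2 Gy centrally
        dose_maps[nominal] = simulate_dose_map(
            nominal, sigma, pitch_mm=config.pitch_mm, peak_dose_gy=peak,
            noise_rel=film_noise, rng=np.random.default_rng(seq))

    frames = []
    read_rngs = read_seed.spawn(len(detectors))
    for det, seq in zip(detectors, read_rngs):
        frames.append(simulate_readings(config, det, np.random.default_rng(seq)))
    readings = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    s_ref = s_true[beams.REFERENCE_FIELD_CM]
    omega_true = {
        nominal: float(sauer_wilbert(s, params) / sauer_wilbert(s_ref, params))
        for nominal, s in s_true.items()
    }
    truth = {
        "seed": config.seed,
        "linac": config.linac,
        "beam": config.beam,
        "penumbra_sigma_mm": sigma,
        "curve": params.as_array().tolist(),
        "s_clin_true": s_true,
        "omega_true": omega_true,
        "clr": config.clr,
        "w1_scale": config.w1_scale,
        "k_true": {
            det: {
                nominal: float(
                    model_kvol(beams.detector(det), nominal * 10.0, sigma)
                    / model_kvol(beams.detector(det),
                                 beams.REFERENCE_FIELD_CM * 10.0, sigma)
                    * evaluate_k(pert, s_true[nominal]))
                for nominal in sorted(config.fields_cm)
            }
            for det, pert in config.detector_perturbations.items()
        },
    }
    return SyntheticCampaign(config=config, dose_maps=dose_maps,
                             readings=readings, truth=truth)
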