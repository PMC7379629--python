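"""Reference beam and detector data anchoring simulations and examples.

The package ships the published characterisation of the two clinical
accelerators it was developed against (an Elekta Versa HD and a Varian
TrueBeam, each with 6/10 MV beams with and without flattening filter):

* ``REFERENCE_CURVES`` — fitted output-factor parameters per beam, used as
  ground-truth curves by the campaign simulator;
* ``MEASURED_SCLIN`` — film-measured equivalent square field sizes for the
  nine nominal fields of each beam;
* ``DEFAULT_PENUMBRA_SIGMA_MM`` — per-beam penumbra widths chosen so a
  simulated 0.5 cm nominal field reproduces that beam's measured
  equivalent square;
* ``DETECTORS`` — lateral active-area geometries of the detectors studied.
"""

from __future__ import annotations

from .output_factors import SauerWilbertParams
from .volume import DetectorGeometry

__all__ = [
    "BEAMS",
    "NOMINAL_FIELDS_CM",
    "REFERENCE_FIELD_CM",
    "REFERENCE_CURVES",
    "MEASURED_SCLIN",
    "DEFAULT_PENUMBRA_SIGMA_MM",
    "DETECTORS",
    "detector",
]

#: (linac, energy-filter) labels of the eight characterised beams
BEAMS: tuple[tuple[str, str], ...] = tuple(
    (linac, beam)
    for linac in ("Elekta Versa HD", "Varian TrueBeam")
    for beam in ("6 MV WFF", "6 MV FFF", "10 MV WFF", "10 MV FFF")
)

#: nominal square field side lengths (cm) of a measurement campaign
NOMINAL_FIELDS_CM = (0.5, 0.8, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 10.0)

REFERENCE_FIELD_CM = 10.0

#: fitted output-factor curve parameters (P_inf, n, l, S_inf, b) per beam
REFERENCE_CURVES: dict[tuple[str, str], SauerWilbertParams] = {
    ("Elekta Versa HD", "6 MV WFF"): SauerWilbertParams(0.751, 2.701, 0.542, 0.384, 0.105),
    ("Elekta Versa HD", "6 MV FFF"): SauerWilbertParams(0.767, 2.614, 0.514, 0.299, 0.151),
    ("Elekta Versa HD", "10 MV WFF"): SauerWilbertParams(0.774, 2.183, 0.578, 0.313, 0.130),
    ("Elekta Versa HD", "10 MV FFF"): SauerWilbertParams(0.829, 1.791, 0.511, 0.198, 0.214),
    ("Varian TrueBeam", "6 MV WFF"): SauerWilbertParams(0.741, 2.646, 0.461, 0.508, 0.072),
    ("Varian TrueBeam", "6 MV FFF"): SauerWilbertParams(0.790, 2.097, 0.419, 1.424, 0.016),
    ("Varian TrueBeam", "10 MV WFF"): SauerWilbertParams(0.816, 1.844, 0.588, 0.478, 0.050),
    ("Varian TrueBeam", "10 MV FFF"): SauerWilbertParams(0.816, 1.904, 0.497, 0.227, 0.173),
}

#: film-measured equivalent square sizes (cm) keyed by beam, then nominal size
MEASURED_SCLIN: dict[tuple[str, str], dict[float, float]] = {
    ("Elekta Versa HD", "6 MV WFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.60, 0.87, 1.03, 1.51, 2.04, 3.06, 4.04, 5.04, 10.04))),
    ("Elekta Versa HD", "6 MV FFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.59, 0.85, 1.03, 1.52, 2.03, 3.04, 4.03, 5.01, 9.94))),
    ("Elekta Versa HD", "10 MV WFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.62, 0.87, 1.06, 1.55, 2.05, 3.08, 4.06, 5.05, 10.05))),
    ("Elekta Versa HD", "10 MV FFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.58, 0.86, 1.04, 1.52, 2.04, 3.02, 4.01, 4.99, 9.90))),
    ("Varian TrueBeam", "6 MV WFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.56, 0.81, 1.01, 1.50, 2.00, 3.03, 4.03, 5.02, 10.03))),
    ("Varian TrueBeam", "6 MV FFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.54, 0.82, 0.99, 1.49, 1.99, 3.00, 3.99, 5.00, 9.96))),
    ("Varian TrueBeam", "10 MV WFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.57, 0.84, 1.03, 1.52, 2.01, 3.00, 4.02, 5.01, 10.02))),
    ("Varian TrueBeam", "10 MV FFF"): dict(zip(NOMINAL_FIELDS_CM,
        (0.55, 0.81, 1.02, 1.51, 1.99, 2.98, 3.98, 4.96, 9.87))),
}

#: penumbra Gaussian sigma (mm) reproducing each beam's measured 0.5 cm Sclin
DEFAULT_PENUMBRA_SIGMA_MM: dict[tuple[str, str], float] = {
    ("Elekta Versa HD", "6 MV WFF"): 1.97,
    ("Elekta Versa HD", "6 MV FFF"): 1.91,
    ("Elekta Versa HD", "10 MV WFF"): 2.05,
    ("Elekta Versa HD", "10 MV FFF"): 1.84,
    ("Varian TrueBeam", "6 MV WFF"): 1.70,
    ("Varian TrueBeam", "6 MV FFF"): 1.58,
    ("Varian TrueBeam", "10 MV WFF"): 1.78,
    ("Varian TrueBeam", "10 MV FFF"): 1.62,
}

#: lateral active-area geometry of every detector handled by the pipeline;
#: "EBT3 ROI" is the 0.5 mm analysis ROI that plays the role of the film's
#: detector area, "W1 PSD" the 1 mm diameter scintillating fibre.
DETECTORS: tuple[DetectorGeometry, ...] = (
    DetectorGeometry("EBT3 ROI", "circular", 0.25),
    DetectorGeometry("W1 PSD", "circular", 0.5),
    DetectorGeometry("IBA SFD diode", "circular", 0.3),
    DetectorGeometry("IBA Razor diode", "circular", 0.3),
    DetectorGeometry("PTW 60008 Diode P", "circular", 0.6),
    DetectorGeometry("PTW 60012 Diode E", "circular", 0.6),
    DetectorGeometry("PTW 60018 Diode SRS", "circular", 0.6),
    DetectorGeometry("SN EDGE Detector", "square", 0.8),
    DetectorGeometry("PTW 60019 mD", "circular", 1.1),
)


def detector(name: str) -> DetectorGeometry:
    """Look up a shipped detector geometry by name."""
    for g in DETECTORS:
        if g.name == name:
            return g
    raise KeyError(f"unknown detector {name!r}")
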