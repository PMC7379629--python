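"""Cerenkov correction and film cross-normalization for the two-channel
plastic scintillator.

The scintillator signal (channel 1, green-weighted) is contaminated by
Cerenkov light generated in the optical fibre; channel 2 (blue-weighted)
reads mostly that contamination.  A two-point calibration with maximal and
minimal fibre length in a 10 cm x 10 cm field gives the Cerenkov light ratio

    CLR = (M_max^Ch1 - M_min^Ch1) / (M_max^Ch2 - M_min^Ch2)

and the corrected signal for any field is ``M = M^Ch1 - CLR * M^Ch2``.

Because scintillator and film measure on different absolute scales, the
scintillator series is divided by the mean signal ratio over the nine
clinical fields (epsilon-bar) before both are fitted jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, CalibrationError

__all__ = [
    "TwoChannelReading",
    "CLRCalibration",
    "compute_clr",
    "cerenkov_correct",
    "cross_normalization",
    "normalize_w1",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoChannelReading:
    """Charges (nC) read simultaneously in both electrometer channels."""

    m_ch1: float
    m_ch2: float
    field_label: str = ""
    energy_label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m_ch1) and np.isfinite(self.m_ch2)):
            raise ValueError("channel readings must be finite")
        if self.m_ch1 < 0:
            raise ValueError("channel-1 reading must be non-negative")


@dataclass(frozen=True)
class CLRCalibration:
    """Cerenkov light ratio for one (linac, energy, filter) combination."""

    clr: float
    energy_label: str = ""
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if not self.clr > 0:
            raise ValueError("CLR must be positive")


def compute_clr(max_reading: TwoChannelReading | Sequence[TwoChannelReading],
                min_reading: TwoChannelReading | Sequence[TwoChannelReading],
                energy_label: str = "") -> CLRCalibration:
    """CLR from max/min fibre-length readings in the reference field.

    With repeated (max, min) pairs the per-repeat CLRs are averaged.  A
    channel-2 span below 1e-12 of the larger channel-2 reading raises
    ``CalibrationError``.
    """
    if isinstance(max_reading, TwoChannelReading):
        max_reading = [max_reading]
    if isinstance(min_reading, TwoChannelReading):
        min_reading = [min_reading]
    if len(max_reading) != len(min_reading) or not max_reading:
        raise CalibrationError("max/min reading series must pair up")
    clrs = []
    for mx, mn in zip(max_reading, min_reading):
        den = mx.m_ch2 - mn.m_ch2
        eps = 1e-12 * max(abs(mx.m_ch2), abs(mn.m_ch2), 1.0)
        if abs(den) <= eps:
            raise CalibrationError("channel-2 span too small: CLR ill-conditioned")
        clrs.append((mx.m_ch1 - mn.m_ch1) / den)
    return CLRCalibration(clr=float(np.mean(clrs)), energy_label=energy_label,
                          n_repeats=len(clrs))


def cerenkov_correct(reading: TwoChannelReading, cal: CLRCalibration) -> float:
    """Cerenkov-corrected scintillator signal ``M_ch1 - CLR * M_ch2``.

    Non-positive results are legitimate with very noisy data; they are
    logged and returned rather than rejected.
    """
    corrected = reading.m_ch1 - cal.clr * reading.m_ch2
    if corrected <= 0:
        log.warning("non-positive Cerenkov-corrected signal %.4g for field %s",
                    corrected, reading.field_label or "<unlabelled>")
    return corrected


def cross_normalization(w1_corrected: Sequence[float],
                        ebt3_corrected: Sequence[float]) -> float:
    """Mean scintillator/film signal ratio over the clinical fields.

    Inputs must already be volume-averaging corrected and aligned field by
    field (conventionally the nine clinical fields of one beam).
    """
    w1 = np.asarray(w1_corrected, dtype=float)
    film = np.asarray(ebt3_corrected, dtype=float)
    if w1.shape != film.shape or w1.ndim != 1 or w1.size == 0:
        raise AlignmentError("series must cover the same fields")
    if np.any(w1 <= 0) or np.any(film <= 0):
        raise AlignmentError("cross-normalization needs positive signals")
    return float(np.mean(w1 / film))


def normalize_w1(corrected_signal: float, kvol_w1: float,
                 epsilon_bar: float) -> float:
    """Scintillator signal, volume-averaging corrected and put on the film scale."""
    if not epsilon_bar > 0:
        raise ValueError("epsilon_bar must be positive")
    return corrected_signal * kvol_w1 / epsilon_bar
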