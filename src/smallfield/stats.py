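"""Two-sample t-tests from summary statistics and uncertainty plumbing.

Dosimetry campaigns rarely retain raw repeats: published comparisons work
from per-field means, 1-SD uncertainties and the (small) number of
measurements.  This module therefore tests from summaries directly, with
either the pooled-variance or the Welch construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats as sps

from .errors import SmallFieldError

__all__ = [
    "SummaryStat",
    "TTestResult",
    "t_test_from_summary",
    "combine_relative_sd",
]


@dataclass(frozen=True)
class SummaryStat:
    """Mean, 1-SD and number of measurements of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 measurements for testing")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    tails: int

    def __post_init__(self) -> None:
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def t_test_from_summary(g1: SummaryStat, g2: SummaryStat, tails: int = 1,
                        variance_mode: str = "welch") -> TTestResult:
    """Two-sample Student's t-test from group summaries.

    ``variance_mode`` is ``"welch"`` (unequal variances, Welch-Satterthwaite
    degrees of freedom) or ``"pooled"``.  The one-tailed p-value tests the
    directional alternative mean2 > mean1.
    """
    if variance_mode not in ("welch", "pooled"):
        raise ValueError("variance_mode must be 'welch' or 'pooled'")
    v1, v2 = g1.sd**2, g2.sd**2
    if v1 == 0 and v2 == 0:
        if g1.mean == g2.mean:
            raise SmallFieldError("degenerate test: zero variance, equal means")
        t = np.inf if g2.mean > g1.mean else -np.inf
        df = g1.n + g2.n - 2
    elif variance_mode == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        t = (g2.mean - g1.mean) / se
    else:
        a, b = v1 / g1.n, v2 / g2.n
        se = np.sqrt(a + b)
        t = (g2.mean - g1.mean) / se
        df = (a + b) ** 2 / (a**2 / (g1.n - 1) + b**2 / (g2.n - 1))
    if tails == 1:
        p = float(sps.t.sf(t, df))
    elif tails == 2:
        p = float(2.0 * sps.t.sf(abs(t), df))
    else:
        raise ValueError("tails must be 1 or 2")
    return TTestResult(t=float(t), df=float(df), p=min(p, 1.0), tails=tails)


def combine_relative_sd(rel_sds: Iterable[float]) -> float:
    """Root-sum-square combination of independent relative SDs."""
    arr = np.asarray(list(rel_sds), dtype=float)
    if np.any(arr < 0):
        raise ValueError("relative SDs must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))
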