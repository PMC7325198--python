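"""Cross-correlation score (CCS) for quantitative diffractogram comparison.

With f'(theta) the normalized diffractogram of a standard and g'(theta) that
of a sample, the patterns are first squared, f = f'^2 and g = g'^2, to
accentuate peaks and attenuate background; the score is then

    CCS = [ sum over lags tau of C_fg(tau) ] / [ same sum of C_ff(tau) ],

where C_fg(tau) is the discrete cross-correlation of f and g and C_ff the
auto-correlation of the standard, integrals discretized as rectangle sums.

Two lag sets are offered.  ``mode="full"`` admits every lag — the literal
definition — but the double sum then factorizes, sum_tau C_fg = (sum f)(sum g),
so the full-lag score reduces to (sum g)/(sum f) and carries no peak-position
information.  ``mode="windowed"`` (the recommended default, |tau| <= max_lag,
0.5 deg 2theta) keeps the score position sensitive while still absorbing
small 2theta misalignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GridMismatch, ZeroDenominator
from .pattern import Pattern

#: Recommended half-width of the lag window, degrees 2theta.
DEFAULT_MAX_LAG = 0.5


@dataclass
class CorrelationFunction:
    """Discrete correlation values indexed by lag tau (degrees 2theta)."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have the same shape")


@dataclass
class CCSResult:
    """A cross-correlation score with the mode and window that produced it."""

    score: float
    mode: str
    max_lag: float
    step: float
    standard_label: str = ""
    sample_label: str = ""


def _check_common_grid(f: Pattern, g: Pattern) -> None:
    if not f.same_grid(g):
        raise GridMismatch("patterns must share a common uniform grid")


def square_pattern(p: Pattern) -> Pattern:
    """Pointwise square of a (normalized) pattern; grid unchanged."""
    return p.replace_intensity(p.intensity**2)


def correlate(f: Pattern, g: Pattern) -> CorrelationFunction:
    """Discrete cross-correlation C[k] = step * sum_i f[i] g[i+k].

    Lags run over k in [-(N-1), N-1] with values outside the support
    treated as zero.
    """
    _check_common_grid(f, g)
    n = len(f)
    vals = f.step * np.correlate(g.intensity, f.intensity, mode="full")
    lags = f.step * np.arange(-(n - 1), n)
    return CorrelationFunction(lags, vals)


def _windowed_lag_sum(f: np.ndarray, g: np.ndarray, kmax: int) -> float:
    """sum over |k| <= kmax of sum_i f[i] g[i+k] (direct sliding dots)."""
    n = len(f)
    total = float(np.dot(f, g))
    for k in range(1, min(kmax, n - 1) + 1):
        total += float(np.dot(f[: n - k], g[k:]))  # positive lag
        total += float(np.dot(f[k:], g[: n - k]))  # negative lag
    return total


def score(
    standard: Pattern,
    sample: Pattern,
    mode: str = "windowed",
    max_lag: float = DEFAULT_MAX_LAG,
    square: bool = True,
) -> CCSResult:
    """Cross-correlation score of ``sample`` against ``standard``.

    Both patterns must be preprocessed, normalized and on a common grid.
    They are squared internally (``square=True``) per the CCS definition.
    """
    _check_common_grid(standard, sample)
    f = standard.intensity**2 if square else standard.intensity
    g = sample.intensity**2 if square else sample.intensity
    step = standard.step
    if mode == "full":
        num = step * float(np.sum(np.correlate(g, f, mode="full")))
        den = step * float(np.sum(np.correlate(f, f, mode="full")))
    elif mode == "windowed":
        if max_lag <= 0:
            raise ValueError("max_lag must be positive in windowed mode")
        kmax = int(np.floor(max_lag / step + 1e-9))
        num = step * _windowed_lag_sum(f, g, kmax)
        den = step * _windowed_lag_sum(f, f, kmax)
    else:
        raise ValueError("mode must be 'full' or 'windowed'")
    if den <= 0.0:
        raise ZeroDenominator("standard pattern is identically zero")
    return CCSResult(
        score=num / den,
        mode=mode,
        max_lag=np.inf if mode == "full" else max_lag,
        step=step,
        standard_label=standard.label,
        sample_label=sample.label,
    )


def score_matrix(
    patterns: Sequence[Pattern],
    mode: str = "windowed",
    max_lag: float = DEFAULT_MAX_LAG,
    square: bool = True,
) -> np.ndarray:
    """Pairwise scores: entry (i, j) = score(patterns[i] as standard,
    patterns[j] as sample).  Diagonal entries equal 1 exactly.

    Note the matrix is generally asymmetric: the denominator is the
    auto-correlation mass of the *standard*.
    """
    pats = list(patterns)
    for q in pats[1:]:
        _check_common_grid(pats[0], q)
    n = len(pats)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = score(pats[i], pats[j], mode=mode, max_lag=max_lag,
                              square=square).score
    return out
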