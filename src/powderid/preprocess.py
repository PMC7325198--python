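"""Diffractogram conditioning: resampling, background, smoothing, Kalpha2
stripping and normalization.

The pipeline order is fixed: resample (if needed) -> fit/subtract background
-> smooth -> strip Kalpha2 -> normalize.  Every stage maps a valid
:class:`~powderid.pattern.Pattern` to a valid Pattern on the same grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateFit,
    GridMismatch,
    RangeError,
    WindowTooLarge,
    ZeroPattern,
)
from .pattern import CU_KALPHA1, CU_KALPHA2, Pattern


@dataclass
class KAlphaParams:
    """CuKalpha doublet constants used for Rachinger stripping."""

    lambda1_angstrom: float = CU_KALPHA1
    lambda2_angstrom: float = CU_KALPHA2
    #: Kalpha2 : Kalpha1 intensity ratio (0.5 for a Cu tube).
    ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError("kalpha ratio must lie in [0, 1]")
        if not (self.lambda2_angstrom > self.lambda1_angstrom > 0.0):
            raise ValueError("need lambda2 > lambda1 > 0")


@dataclass
class PreprocessParams:
    """Tunable parameters of the conditioning pipeline.

    Defaults: degree-5 iteratively clipped polynomial background
    (tol 1e-6, <= 100 iterations); 11-point order-3 Savitzky-Golay smoothing
    (about 0.2 deg 2theta on a 0.019 deg grid, below typical peak FWHM);
    CuKalpha doublet constants with ratio 0.5; unit-maximum normalization.
    """

    bg_degree: int = 5
    bg_max_iter: int = 100
    bg_tol: float = 1e-6
    smooth_window: int = 11
    smooth_order: int = 3
    kalpha: KAlphaParams = field(default_factory=KAlphaParams)
    norm_mode: str = "unit_max"

    def __post_init__(self) -> None:
        if self.bg_degree < 0 or self.bg_max_iter < 1 or self.bg_tol <= 0:
            raise ValueError("invalid background parameters")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_order:
            raise ValueError("smooth_window must be odd and > smooth_order")
        if self.norm_mode not in ("unit_max", "unit_area"):
            raise ValueError("norm_mode must be 'unit_max' or 'unit_area'")


def resample(p: Pattern, start: float, stop: float, step: float) -> Pattern:
    """Linearly interpolate a pattern onto a uniform target grid.

    The target may extend beyond the source range by at most one source step
    (edge values are held); anything further raises :class:`RangeError`.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start > stop:
        raise ValueError("start must not exceed stop")
    lo, hi = p.two_theta[0], p.two_theta[-1]
    if start < lo - p.step or stop > hi + p.step:
        raise RangeError(
            f"target [{start}, {stop}] extends beyond source [{lo}, {hi}] "
            "by more than one step"
        )
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    grid = start + step * np.arange(n)
    y = np.interp(grid, p.two_theta, p.intensity)
    return Pattern(grid, y, dict(p.meta))


def fit_background(p: Pattern, params: PreprocessParams) -> Pattern:
    """Estimate the background by iteratively clipped polynomial fitting.

    A plain least-squares polynomial is biased upward by the peaks; here each
    iteration refits after replacing points above the current fit by the fit,
    which converges onto the peak-free envelope.
    """
    if params.bg_degree >= len(p) / 4:
        raise ValueError("bg_degree must be < length(pattern)/4")
    # Chebyshev basis on [-1, 1] keeps the normal equations well conditioned;
    # the projector is precomputed once, so each clipping pass is two matmuls.
    x = p.two_theta
    u = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    design = np.polynomial.chebyshev.chebvander(u, params.bg_degree)
    if np.linalg.matrix_rank(design) < params.bg_degree + 1:
        raise DegenerateFit("rank-deficient background fit")
    projector = np.linalg.pinv(design)
    y = p.intensity.copy()
    bg_prev = None
    bg = y
    for _ in range(params.bg_max_iter):
        bg = design @ (projector @ y)
        if bg_prev is not None:
            scale = max(float(np.max(np.abs(bg_prev))), 1e-300)
            if float(np.max(np.abs(bg - bg_prev))) < params.bg_tol * scale:
                break
        bg_prev = bg
        y = np.minimum(y, bg)
    return p.replace_intensity(bg)


def subtract_background(p: Pattern, bg: Pattern) -> Pattern:
    """Pointwise ``max(p - bg, 0)`` on identical grids."""
    if not p.same_grid(bg):
        raise GridMismatch("pattern and background grids differ")
    return p.replace_intensity(np.clip(p.intensity - bg.intensity, 0.0, None))


def smooth(p: Pattern, params: PreprocessParams) -> Pattern:
    """Savitzky-Golay smoothing; polynomials of degree <= smooth_order are
    reproduced exactly (edges by polynomial extrapolation of the end fits)."""
    if params.smooth_window > len(p):
        raise WindowTooLarge(
            f"smooth_window {params.smooth_window} exceeds pattern length {len(p)}"
        )
    y = savgol_filter(
        p.intensity, params.smooth_window, params.smooth_order, mode="interp"
    )
    return p.replace_intensity(y)


def strip_kalpha2(p: Pattern, params: PreprocessParams) -> Pattern:
    """Remove the Kalpha2 component by Rachinger-type stripping.

    For every grid angle t2 the Kalpha2 contribution equals ``ratio`` times
    the (already stripped) Kalpha1 intensity at the source angle
    ``t1 = 2 asin((lambda1/lambda2) sin(t2/2))`` (Bragg's law: same lattice
    spacing, shorter wavelength).  The stripped signal K satisfies

        K(t2) = observed(t2) - ratio * K(t1(t2)),

    solved here by damped fixed-point iteration (a contraction for
    ratio < 1); angles whose source falls below the grid contribute nothing.
    Negative residuals are clipped at zero.
    """
    ka = params.kalpha
    wl = p.meta.get("wavelength_angstrom")
    if wl is not None and not (
        abs(wl - ka.lambda1_angstrom) < 0.01 or abs(wl - 1.5418) < 0.01
    ):
        raise ValueError(
            f"pattern wavelength {wl} inconsistent with Kalpha1 "
            f"{ka.lambda1_angstrom}"
        )
    if ka.ratio == 0.0:
        return p.copy()
    t = p.two_theta
    s = (ka.lambda1_angstrom / ka.lambda2_angstrom) * np.sin(np.radians(t / 2.0))
    t1 = 2.0 * np.degrees(np.arcsin(s))  # always <= t since lambda1 < lambda2
    obs = p.intensity
    out = obs.copy()
    tol = 1e-12 * max(float(np.max(np.abs(obs))), 1.0)
    for _ in range(200):
        k1 = np.interp(t1, t, out, left=0.0, right=0.0)
        new = np.clip(obs - ka.ratio * k1, 0.0, None)
        delta = float(np.max(np.abs(new - out)))
        out = new
        if delta < tol:
            break
    return p.replace_intensity(out)


def normalize(p: Pattern, params: PreprocessParams | None = None, mode: str | None = None) -> Pattern:
    """Scale intensities to unit maximum (default) or unit area."""
    mode = mode or (params.norm_mode if params is not None else "unit_max")
    m = float(np.max(p.intensity))
    if m <= 0.0:
        raise ZeroPattern("cannot normalize: maximum intensity is zero")
    if mode == "unit_max":
        return p.replace_intensity(p.intensity / m)
    if mode == "unit_area":
        area = float(np.sum(p.intensity)) * p.step
        return p.replace_intensity(p.intensity / area)
    raise ValueError(f"unknown norm_mode {mode!r}")


def preprocess(
    p: Pattern,
    params: PreprocessParams | None = None,
    *,
    background: bool = True,
    smoothing: bool = True,
    kalpha2: bool = True,
    normalization: bool = True,
) -> Pattern:
    """Run the full conditioning pipeline; each stage can be toggled off."""
    params = params or PreprocessParams()
    out = p
    if background:
        out = subtract_background(out, fit_background(out, params))
    if smoothing:
        out = smooth(out, params)
        out = out.replace_intensity(np.clip(out.intensity, 0.0, None))
    if kalpha2:
        out = strip_kalpha2(out, params)
    if normalization:
        out = normalize(out, params)
    return out
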