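"""Synthetic diffractogram generator.

Emulates a Bragg-Brentano CuKalpha laboratory instrument: pseudo-Voigt
reflection profiles on a uniform 5-60 deg 2theta grid with 0.019 deg steps,
an optional Kalpha1/Kalpha2 doublet placed by Bragg's law, a polynomial
background, Poisson counting noise, and lognormal per-peak intensity
perturbations standing in for preferred-orientation / crystal-habit effects
(which change relative intensities but never peak positions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import BadWeights, GridMismatch, ReflectionOutOfRange
from .pattern import CU_KALPHA1, CU_KALPHA2, Pattern, Phase, convert_two_theta

_LN2 = np.log(2.0)


@dataclass
class GridSpec:
    """Uniform 2theta measurement grid (degrees)."""

    start: float = 5.0
    stop: float = 60.0
    step: float = 0.019

    def __post_init__(self) -> None:
        if not (self.start < self.stop and self.step > 0):
            raise ValueError("need start < stop and step > 0")

    def axis(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)


@dataclass
class SimConfig:
    """Instrument and sample model for :func:`render`.

    ``noise_scale`` sets the counting statistics: observed counts are drawn
    Poisson with mean ``noise_scale`` times the noiseless signal, i.e. the
    expected counts at unit clean intensity; 0 disables noise.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    fwhm: float = 0.1
    eta: float = 0.5
    doublet: bool = True
    lambda1_angstrom: float = CU_KALPHA1
    lambda2_angstrom: float = CU_KALPHA2
    kalpha_ratio: float = 0.5
    bg_coeffs: tuple = (50.0,)
    noise_scale: float = 1.0
    intensity_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fwhm < 2.0 * self.grid.step:
            raise ValueError("fwhm must be at least two grid steps")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")
        if self.noise_scale < 0 or self.intensity_sigma < 0:
            raise ValueError("noise_scale and intensity_sigma must be >= 0")


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-area pseudo-Voigt profile: eta*Lorentzian + (1-eta)*Gaussian."""
    dx = x - center
    gauss = (2.0 / fwhm) * np.sqrt(_LN2 / np.pi) * np.exp(-4.0 * _LN2 * (dx / fwhm) ** 2)
    lorentz = (2.0 / (np.pi * fwhm)) / (1.0 + 4.0 * (dx / fwhm) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def kalpha2_position(two_theta: float | np.ndarray, lambda1: float = CU_KALPHA1,
                     lambda2: float = CU_KALPHA2) -> np.ndarray:
    """Kalpha2 companion position of a Kalpha1 reflection (Bragg's law)."""
    s = np.minimum(1.0, (lambda2 / lambda1) * np.sin(np.radians(np.asarray(two_theta) / 2.0)))
    return 2.0 * np.degrees(np.arcsin(s))


def render(phase: Phase, config: SimConfig | None = None) -> Pattern:
    """Render a phase into a synthetic diffractogram.

    Each reflection contributes a pseudo-Voigt with area proportional to its
    relative intensity (physically conventional, and it makes mixture weights
    interpretable); the Kalpha2 companion carries ``kalpha_ratio`` times the
    Kalpha1 area.  Reflections outside the grid raise a
    :class:`ReflectionOutOfRange` warning and are skipped.
    """
    config = config or SimConfig()
    t = config.grid.axis()
    clean = np.zeros_like(t)

    positions = phase.positions
    if abs(phase.ref_wavelength_angstrom - config.lambda1_angstrom) > 1e-9:
        positions, ok = convert_two_theta(
            positions, phase.ref_wavelength_angstrom, config.lambda1_angstrom
        )
        rels = phase.rel_intensities[ok]
        positions = positions[ok]
    else:
        rels = phase.rel_intensities

    for pos, rel in zip(positions, rels):
        if not (t[0] <= pos <= t[-1]):
            warnings.warn(
                f"reflection at {pos:.3f} deg outside grid "
                f"[{t[0]:.3f}, {t[-1]:.3f}]; skipped",
                ReflectionOutOfRange,
                stacklevel=2,
            )
            continue
        clean += rel * pseudo_voigt(t, pos, config.fwhm, config.eta)
        if config.doublet:
            pos2 = float(kalpha2_position(pos, config.lambda1_angstrom,
                                          config.lambda2_angstrom))
            if t[0] <= pos2 <= t[-1]:
                clean += config.kalpha_ratio * rel * pseudo_voigt(
                    t, pos2, config.fwhm, config.eta
                )

    if config.bg_coeffs:
        clean += np.polynomial.polynomial.polyval(t, np.asarray(config.bg_coeffs))
    clean = np.clip(clean, 0.0, None)

    if config.noise_scale > 0:
        rng = np.random.default_rng(config.seed)
        y = rng.poisson(config.noise_scale * clean).astype(float)
    else:
        y = clean

    meta = {"wavelength_angstrom": config.lambda1_angstrom, "label": phase.name}
    return Pattern(t, y, meta)


def perturb_intensities(phase: Phase, sigma: float, seed: int) -> Phase:
    """Multiply each relative intensity by an independent lognormal factor
    (median 1, log-scale sd ``sigma``); positions are untouched and the
    result is rescaled so the strongest line is 100.

    This is an empirical stand-in for preferred orientation and grinding
    effects, which alter relative intensities but not peak positions.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, sigma, size=len(phase)))
    return Phase(
        phase.name,
        phase.positions.copy(),
        phase.rel_intensities * factors,
        phase.ref_wavelength_angstrom,
    )


def mix_patterns(patterns: Sequence[Pattern], weights: Sequence[float]) -> Pattern:
    """Pointwise weighted sum of patterns on a common grid.

    Weights must be positive and sum to 1 (an adulterated street sample,
    e.g. 30% active substance + 70% diluent).
    """
    pats = list(patterns)
    w = np.asarray(list(weights), float)
    if len(pats) != len(w) or len(pats) == 0:
        raise BadWeights("need one positive weight per pattern")
    if np.any(w <= 0) or abs(float(w.sum()) - 1.0) > 1e-9:
        raise BadWeights("weights must be positive and sum to 1")
    for q in pats[1:]:
        if not pats[0].same_grid(q):
            raise GridMismatch("mixture patterns must share one grid")
    y = np.zeros_like(pats[0].intensity)
    for wi, pi in zip(w, pats):
        y = y + wi * pi.intensity
    meta = dict(pats[0].meta)
    meta["label"] = "mix(" + "+".join(
        f"{wi:g}*{pi.label or 'pattern'}" for wi, pi in zip(w, pats)
    ) + ")"
    return Pattern(pats[0].two_theta, y, meta)


def fixture_library(
    n_phases: int,
    seed: int,
    grid: GridSpec | None = None,
    min_separation: float = 0.3,
) -> list[Phase]:
    """Generate a reproducible reference library of synthetic phases.

    Each phase carries 8-25 reflections placed uniformly inside the grid with
    at least ``min_separation`` deg 2theta between lines, and lognormal
    relative intensities (median 30, clipped to [10, 100] before rescaling,
    like a PDF card that tabulates lines above a relative-intensity floor).
    Phases 0 and 1 form a deliberately similar pair sharing half of phase 0's
    positions — the structural-analog stress case typical of designer drugs.
    """
    if n_phases < 2:
        raise ValueError("n_phases must be >= 2")
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    lo, hi = grid.start + 2.0, grid.stop - 3.0

    def draw_positions(n: int, fixed: np.ndarray | None = None) -> np.ndarray:
        taken: list[float] = [] if fixed is None else list(fixed)
        out: list[float] = []
        attempts = 0
        while len(out) < n and attempts < 20000:
            cand = float(rng.uniform(lo, hi))
            attempts += 1
            if all(abs(cand - q) >= min_separation for q in taken):
                taken.append(cand)
                out.append(cand)
        return np.asarray(sorted(out))

    def draw_intensities(n: int) -> np.ndarray:
        raw = np.exp(rng.normal(np.log(30.0), 0.8, size=n))
        return np.clip(raw, 10.0, 100.0)

    phases: list[Phase] = []
    n0 = int(rng.integers(8, 26))
    pos0 = draw_positions(n0)
    phases.append(Phase("phase_00", pos0, draw_intensities(len(pos0))))

    # Structural analog: shares half of phase 0's lines exactly.
    n_shared = max(1, len(pos0) // 2)
    shared = np.sort(rng.choice(pos0, size=n_shared, replace=False))
    n_own = max(int(rng.integers(8, 26)) - n_shared, 4)
    own = draw_positions(n_own, fixed=shared)
    pos1 = np.sort(np.concatenate([shared, own]))
    phases.append(Phase("phase_01", pos1, draw_intensities(len(pos1))))

    for i in range(2, n_phases):
        n_i = int(rng.integers(8, 26))
        pos = draw_positions(n_i)
        phases.append(Phase(f"phase_{i:02d}", pos, draw_intensities(len(pos))))
    return phases
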