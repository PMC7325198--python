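"""Core containers: diffraction patterns and reference phases.

A :class:`Pattern` is a powder diffractogram sampled on a strictly increasing,
uniform 2theta grid (degrees) with nonnegative-or-finite intensities (counts or
arbitrary units).  A :class:`Phase` is a reference substance described by its
reflection list — (position in degrees 2theta at a stated wavelength, relative
intensity scaled so the strongest line is 100) — the same information a powder
diffraction file (PDF) card tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import NonMonotoneGrid, NonUniformGrid, TooFewPoints

#: Weighted mean CuKalpha wavelength (Angstrom), the usual single-line value.
CU_KALPHA = 1.5418
#: CuKalpha1 wavelength (Angstrom).
CU_KALPHA1 = 1.540562
#: CuKalpha2 wavelength (Angstrom).
CU_KALPHA2 = 1.544398

#: Minimum number of grid points for a valid diffractogram.
MIN_POINTS = 8

#: Allowed deviation of any grid spacing from the mean step, relative to the step.
GRID_RTOL = 1e-6


@dataclass
class Pattern:
    """A diffractogram on a uniform 2theta grid.

    Parameters
    ----------
    two_theta
        Strictly increasing, uniformly spaced angles in degrees 2theta.
    intensity
        Intensities (same length), all finite.
    meta
        Free-form metadata; recognised keys are ``wavelength_angstrom``,
        ``label`` and ``step`` (degrees 2theta, filled in automatically).
    """

    two_theta: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.two_theta.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("two_theta and intensity must be 1-D")
        if len(self.two_theta) != len(self.intensity):
            raise ValueError("two_theta and intensity lengths differ")
        if len(self.two_theta) < MIN_POINTS:
            raise TooFewPoints(
                f"need >= {MIN_POINTS} points, got {len(self.two_theta)}"
            )
        diffs = np.diff(self.two_theta)
        if np.any(diffs <= 0):
            raise NonMonotoneGrid("two_theta must be strictly increasing")
        step = float(np.mean(diffs))
        if np.max(np.abs(diffs - step)) > GRID_RTOL * step:
            raise NonUniformGrid(
                "grid spacing is not uniform to within "
                f"{GRID_RTOL:g} of the step; resample explicitly"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        self.meta = dict(self.meta)
        self.meta["step"] = step

    # -- convenience accessors -------------------------------------------------

    @property
    def step(self) -> float:
        """Grid spacing in degrees 2theta."""
        return float(self.meta["step"])

    @property
    def label(self) -> str:
        return str(self.meta.get("label", ""))

    @property
    def wavelength(self) -> float:
        """Wavelength in Angstrom (weighted CuKalpha by default)."""
        return float(self.meta.get("wavelength_angstrom", CU_KALPHA))

    def __len__(self) -> int:
        return len(self.two_theta)

    def copy(self) -> "Pattern":
        return Pattern(self.two_theta.copy(), self.intensity.copy(), dict(self.meta))

    def replace_intensity(self, intensity: np.ndarray) -> "Pattern":
        """New Pattern on the same grid with different intensities."""
        return Pattern(self.two_theta, np.asarray(intensity, float), dict(self.meta))

    def same_grid(self, other: "Pattern", rtol: float = 1e-9) -> bool:
        """True when both patterns share the same grid to within ``rtol`` steps."""
        if len(self) != len(other):
            return False
        return bool(
            np.max(np.abs(self.two_theta - other.two_theta)) <= rtol * self.step
        )


@dataclass
class Phase:
    """A reference phase: named reflection list at a stated wavelength.

    Reflections are sorted by position on construction and relative
    intensities rescaled so the strongest equals 100, matching how PDF cards
    are tabulated.
    """

    name: str
    positions: np.ndarray
    rel_intensities: np.ndarray
    ref_wavelength_angstrom: float = CU_KALPHA

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        rel = np.asarray(self.rel_intensities, dtype=float)
        if pos.shape != rel.shape or pos.ndim != 1:
            raise ValueError("positions and rel_intensities must match in shape")
        if len(pos) and (pos.min() <= 0.0 or pos.max() >= 180.0):
            raise ValueError("reflection positions must lie in (0, 180) deg 2theta")
        if len(rel) and rel.min() <= 0.0:
            raise ValueError("relative intensities must be positive")
        if self.ref_wavelength_angstrom <= 0:
            raise ValueError("wavelength must be positive")
        order = np.argsort(pos, kind="stable")
        pos, rel = pos[order], rel[order]
        if len(rel):
            rel = rel * (100.0 / rel.max())
        self.positions = pos
        self.rel_intensities = rel

    @classmethod
    def from_reflections(
        cls,
        name: str,
        reflections: "list[tuple[float, float]]",
        ref_wavelength_angstrom: float = CU_KALPHA,
    ) -> "Phase":
        arr = np.asarray(reflections, dtype=float).reshape(-1, 2)
        return cls(name, arr[:, 0], arr[:, 1], ref_wavelength_angstrom)

    @property
    def reflections(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.positions.tolist(), self.rel_intensities.tolist()))

    def __len__(self) -> int:
        return len(self.positions)


def convert_two_theta(
    positions: np.ndarray, wl_from: float, wl_to: float
) -> tuple[np.ndarray, np.ndarray]:
    """Move Bragg peak positions between wavelengths.

    Uses lambda = 2 d sin(theta): the lattice spacing d is wavelength
    independent, so sin(theta_to) = (wl_to / wl_from) sin(theta_from).

    Returns
    -------
    converted, reachable
        Converted positions (degrees 2theta, NaN where unreachable) and a
        boolean mask of reflections that exist at the target wavelength
        (sin(theta) <= 1).
    """
    pos = np.asarray(positions, dtype=float)
    s = (wl_to / wl_from) * np.sin(np.radians(pos / 2.0))
    ok = np.abs(s) <= 1.0
    out = np.full_like(pos, np.nan)
    out[ok] = 2.0 * np.degrees(np.arcsin(s[ok]))
    return out, ok
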