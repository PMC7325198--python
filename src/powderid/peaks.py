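"""Peak detection, position matching, and phase identification.

Identification follows forensic XRPD practice: peak *positions* are the
substance fingerprint, while relative intensities vary with crystal habit,
preferred orientation and grinding and are therefore never used to reject a
match.  Ties in the fraction of matched positions are broken by the windowed
cross-correlation score against an ideal rendered pattern, and sample peaks
with no counterpart in the reference are surfaced as possible adulterants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from . import ccs, simulate
from .errors import EmptyLibrary, EmptyStandard
from .pattern import Pattern, Phase, convert_two_theta
from .preprocess import PreprocessParams, preprocess

#: Default position tolerance for peak matching, degrees 2theta
#: (about five 0.019 deg grid steps).
DEFAULT_TOLERANCE = 0.10
DEFAULT_MIN_REL_HEIGHT = 0.01
DEFAULT_MIN_REL_PROMINENCE = 0.005


@dataclass
class PeakList:
    """Detected (or tabulated) peaks of one pattern, sorted by position."""

    positions: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.heights = np.asarray(self.heights, float)
        self.prominences = np.asarray(self.prominences, float)
        if not (len(self.positions) == len(self.heights) == len(self.prominences)):
            raise ValueError("positions/heights/prominences lengths differ")
        if np.any(np.diff(self.positions) < 0):
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.heights = self.heights[order]
            self.prominences = self.prominences[order]

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class MatchReport:
    """Outcome of matching a sample peak list against one reference phase."""

    candidate: str
    tolerance: float
    matched: list = field(default_factory=list)  # (standard_pos, sample_pos, delta)
    fraction_matched: float = 0.0
    extra_sample_peaks: list = field(default_factory=list)
    n_standard: int = 0
    tiebreak_ccs: float | None = None

    def to_dict(self) -> dict:
        return {
            "candidate": self.candidate,
            "tolerance": self.tolerance,
            "fraction_matched": self.fraction_matched,
            "n_standard": self.n_standard,
            "matched": [list(m) for m in self.matched],
            "extra_sample_peaks": list(self.extra_sample_peaks),
            "tiebreak_ccs": self.tiebreak_ccs,
        }


def detect_peaks(
    p: Pattern,
    min_rel_height: float = DEFAULT_MIN_REL_HEIGHT,
    min_rel_prominence: float = DEFAULT_MIN_REL_PROMINENCE,
) -> PeakList:
    """Find local maxima above relative height/prominence thresholds.

    Positions are refined by fitting a parabola through the apex sample and
    its two neighbours (sub-step accuracy); heights are read at the apex of
    the smoothed trace, the convention used by search-match software.
    A flat pattern yields an empty list.
    """
    y = p.intensity
    m = float(np.max(y)) if len(y) else 0.0
    if m <= 0.0:
        return PeakList(np.array([]), np.array([]), np.array([]), p.label)
    idx, props = find_peaks(
        y, height=min_rel_height * m, prominence=min_rel_prominence * m
    )
    positions = p.two_theta[idx].astype(float)
    for k, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            if denom < 0.0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                positions[k] = p.two_theta[i] + delta * p.step
    return PeakList(positions, y[idx], props["prominences"], p.label)


def match_peaks(
    sample: PeakList, standard: PeakList, tolerance: float = DEFAULT_TOLERANCE
) -> MatchReport:
    """Greedy nearest-neighbour pairing of peak positions within a tolerance.

    Closest pairs are committed first and each peak is used at most once;
    distance ties break toward the lower angle, making the pairing
    deterministic and order independent.  ``fraction_matched`` counts matched
    *standard* peaks; unpaired sample peaks are reported as
    ``extra_sample_peaks`` (possible adulterants).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(standard) == 0:
        raise EmptyStandard("standard peak list is empty")

    cands = [
        (abs(sp - qp), float(qp), float(sp), i, j)
        for i, qp in enumerate(standard.positions)
        for j, sp in enumerate(sample.positions)
        if abs(sp - qp) <= tolerance
    ]
    cands.sort()
    used_std: set[int] = set()
    used_smp: set[int] = set()
    matched: list[tuple[float, float, float]] = []
    for dist, qp, sp, i, j in cands:
        if i in used_std or j in used_smp:
            continue
        used_std.add(i)
        used_smp.add(j)
        matched.append((qp, sp, sp - qp))
    matched.sort()
    extras = [float(sp) for j, sp in enumerate(sample.positions) if j not in used_smp]
    return MatchReport(
        candidate=standard.source_label,
        tolerance=tolerance,
        matched=matched,
        fraction_matched=len(matched) / len(standard),
        extra_sample_peaks=extras,
        n_standard=len(standard),
    )


def phase_peaklist(phase: Phase, wavelength: float) -> PeakList:
    """Ideal peak list of a phase at a target wavelength (Bragg conversion);
    reflections unreachable at that wavelength are dropped."""
    pos, ok = convert_two_theta(
        phase.positions, phase.ref_wavelength_angstrom, wavelength
    )
    rel = phase.rel_intensities[ok] / 100.0
    return PeakList(pos[ok], rel, rel, phase.name)


def identify(
    sample: Pattern,
    library: Sequence[Phase],
    params: PreprocessParams | None = None,
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    min_rel_height: float = DEFAULT_MIN_REL_HEIGHT,
    min_rel_prominence: float = DEFAULT_MIN_REL_PROMINENCE,
    ccs_max_lag: float = ccs.DEFAULT_MAX_LAG,
    preprocessed: bool = False,
    fwhm: float = 0.1,
) -> list[MatchReport]:
    """Rank library phases against a sample diffractogram.

    The sample is preprocessed (unless ``preprocessed=True``), its peaks
    detected, and each phase's ideal peak list — Bragg-converted to the
    sample's wavelength — matched by position.  Phases are ranked by
    ``fraction_matched``; exact ties are broken by the windowed CCS of the
    sample against a clean render of the tied phase on the sample's grid.
    """
    library = list(library)
    if not library:
        raise EmptyLibrary("phase library is empty")
    params = params or PreprocessParams()
    proc = sample if preprocessed else preprocess(sample, params)
    sample_peaks = detect_peaks(proc, min_rel_height, min_rel_prominence)
    wl = proc.wavelength

    reports = [
        match_peaks(sample_peaks, phase_peaklist(ph, wl), tolerance)
        for ph in library
    ]

    # Break fraction_matched ties with the windowed CCS against a clean render.
    by_frac: dict[float, list[int]] = {}
    for k, rep in enumerate(reports):
        by_frac.setdefault(round(rep.fraction_matched, 12), []).append(k)
    grid = simulate.GridSpec(
        float(proc.two_theta[0]), float(proc.two_theta[-1]) + proc.step / 2, proc.step
    )
    cfg = simulate.SimConfig(
        grid=grid, fwhm=fwhm, doublet=False, bg_coeffs=(), noise_scale=0.0,
        lambda1_angstrom=wl, lambda2_angstrom=wl + 0.004,
    )
    for frac, idxs in by_frac.items():
        if len(idxs) < 2 or frac == 0.0:
            continue
        for k in idxs:
            ideal = simulate.render(library[k], cfg)
            if float(np.max(ideal.intensity)) <= 0.0:
                reports[k].tiebreak_ccs = 0.0
                continue
            ideal = ideal.replace_intensity(ideal.intensity / np.max(ideal.intensity))
            reports[k].tiebreak_ccs = ccs.score(
                ideal, proc, mode="windowed", max_lag=ccs_max_lag
            ).score

    def sort_key(rep: MatchReport):
        tb = rep.tiebreak_ccs if rep.tiebreak_ccs is not None else 0.0
        return (-rep.fraction_matched, -tb, rep.candidate)

    return sorted(reports, key=sort_key)
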