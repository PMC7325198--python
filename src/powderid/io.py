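"""Plain-text input/output for diffractograms and phase libraries.

Diffractograms use the two-column XY ("ASC") dialect: optional ``#``-prefixed
header lines, then one ``angle intensity`` pair per line, whitespace- or
comma-separated.  Phase libraries are delimited text with columns
``phase_name, position_2theta, rel_intensity`` and an optional per-phase
``wavelength_angstrom`` column.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyLibrary,
    IOFailure,
    NonMonotoneGrid,
    NonUniformGrid,
    ParseError,
    TooFewPoints,
)
from .pattern import CU_KALPHA, MIN_POINTS, Pattern, Phase

# Grid jitter up to this fraction of a step is attributed to text round-off
# and snapped onto an exact uniform grid; anything larger must be resampled.
_SNAP_TOL = 1e-2

_META_KEYS = ("label", "wavelength_angstrom")


def _parse_row(line: str) -> tuple[float, float] | None:
    toks = line.replace(",", " ").split()
    if len(toks) < 2:
        return None
    try:
        return float(toks[0]), float(toks[1])
    except ValueError:
        return None


def read_xy(path: str | Path, allow_headers: bool = True) -> Pattern:
    """Read a two-column XY/ASC diffractogram.

    ``#`` lines are always treated as comments; with ``allow_headers``,
    arbitrary non-numeric leading lines are skipped as well.  Header comments
    of the form ``# key: value`` populate ``meta`` for recognised keys.

    Raises
    ------
    TooFewPoints, NonMonotoneGrid, NonUniformGrid, ParseError, IOFailure
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc

    meta: dict = {}
    angles: list[float] = []
    counts: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                if key.strip() in _META_KEYS:
                    key = key.strip()
                    val = val.strip()
                    meta[key] = float(val) if key == "wavelength_angstrom" else val
            continue
        row = _parse_row(line)
        if row is None:
            if allow_headers and not angles:
                continue  # leading free-text header
            raise ParseError(f"{path}:{lineno}: malformed numeric row: {raw!r}")
        angles.append(row[0])
        counts.append(row[1])

    if len(angles) < MIN_POINTS:
        raise TooFewPoints(f"{path}: found {len(angles)} rows, need >= {MIN_POINTS}")

    t = np.asarray(angles)
    y = np.asarray(counts)
    if np.any(np.diff(t) <= 0):
        raise NonMonotoneGrid(f"{path}: 2theta values are not strictly increasing")

    # Snap text round-off back onto an exact uniform grid.
    step = (t[-1] - t[0]) / (len(t) - 1)
    grid = t[0] + step * np.arange(len(t))
    if np.max(np.abs(t - grid)) > _SNAP_TOL * step:
        raise NonUniformGrid(
            f"{path}: grid jitter exceeds {_SNAP_TOL:.0%} of the step; "
            "resample explicitly (preprocess.resample)"
        )
    meta.setdefault("label", path.stem)
    return Pattern(grid, y, meta)


def write_xy(p: Pattern, path: str | Path) -> None:
    """Write a Pattern in the XY dialect (8 significant digits).

    Metadata is preserved in ``# key: value`` header comments, so
    ``read_xy(write_xy(p))`` reproduces ``p`` to text round-off.
    """
    path = Path(path)
    buf = _io.StringIO()
    if p.label:
        buf.write(f"# label: {p.label}\n")
    buf.write(f"# wavelength_angstrom: {p.wavelength:.8g}\n")
    for t, y in zip(p.two_theta, p.intensity):
        buf.write(f"{t:.8g} {y:.8g}\n")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc


def read_phase_library(path: str | Path) -> list[Phase]:
    """Read a delimited phase library into a list of :class:`Phase`.

    Relative intensities are rescaled per phase so the strongest line is 100.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except OSError as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"cannot parse phase library {path}: {exc}") from exc

    df.columns = [str(c).strip() for c in df.columns]
    required = {"phase_name", "position_2theta", "rel_intensity"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: phase library needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    phases: list[Phase] = []
    for name, grp in df.groupby("phase_name", sort=False):
        wl = CU_KALPHA
        if "wavelength_angstrom" in grp.columns:
            wl = float(grp["wavelength_angstrom"].iloc[0])
        try:
            phases.append(
                Phase(
                    str(name),
                    grp["position_2theta"].to_numpy(float),
                    grp["rel_intensity"].to_numpy(float),
                    wl,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: phase {name!r}: {exc}") from exc
    if not phases:
        raise EmptyLibrary(f"{path}: no phases found")
    return phases


def write_phase_library(phases: Sequence[Phase], path: str | Path) -> None:
    """Write phases as delimited text readable by :func:`read_phase_library`."""
    rows = [
        {
            "phase_name": ph.name,
            "position_2theta": pos,
            "rel_intensity": rel,
            "wavelength_angstrom": ph.ref_wavelength_angstrom,
        }
        for ph in phases
        for pos, rel in ph.reflections
    ]
    try:
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
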