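"""Domain types for grids and curves, plus CSV readers/writers.

Functional observations live on a shared one-dimensional grid; by convention
the domain is time normalised to percent of the stance phase, ``[0, 100]``
discretised with 101 equally spaced points, but any strictly increasing real
grid is accepted.  All subsets of the domain are reported as closed position
intervals in domain units, never as indices.

Files are comma-separated UTF-8 with a header row and dot decimals.  Floats
are serialised at full (shortest round-trip) precision so write/read
round-trips are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, FormatError, GridError

__all__ = [
    "DomainGrid",
    "Curve",
    "MeanFunctionPair",
    "read_mean_pair",
    "write_mean_pair",
    "resample_to_grid",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

DEFAULT_SPAN = (0.0, 100.0)
DEFAULT_N_POINTS = 101


@dataclass(frozen=True)
class DomainGrid:
    """Ordered real positions discretising the domain.

    Parameters
    ----------
    points
        Strictly increasing positions in domain units (percent of stance
        phase by default).
    """

    points: np.ndarray

    def __init__(self, points: Sequence[float] | np.ndarray | None = None):
        if points is None:
            points = np.linspace(*DEFAULT_SPAN, DEFAULT_N_POINTS)
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise GridError("grid must be a non-empty 1-D sequence of positions")
        if not np.all(np.isfinite(pts)):
            raise GridError("grid positions must be finite")
        if pts.size > 1 and not np.all(np.diff(pts) > 0):
            raise GridError("grid positions must be strictly increasing")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> int:
        return int(self.points.size)

    @property
    def span(self) -> float:
        """Total domain length (0 for a single-point domain)."""
        return float(self.points[-1] - self.points[0])

    @property
    def spacing(self) -> float:
        """Common spacing; raises if the grid is not equally spaced."""
        if self.length < 2:
            raise GridError("spacing undefined for a single-point grid")
        d = np.diff(self.points)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise GridError("grid is not equally spaced")
        return float(d[0])

    def is_uniform(self) -> bool:
        if self.length < 2:
            return True
        d = np.diff(self.points)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-12))

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length

    def __eq__(self, other) -> bool:
        return isinstance(other, DomainGrid) and np.array_equal(
            self.points, other.points
        )

    def __hash__(self) -> int:
        return hash(self.points.tobytes())


@dataclass(frozen=True)
class Curve:
    """A single function sampled on a :class:`DomainGrid`."""

    grid: DomainGrid
    values: np.ndarray

    def __init__(self, grid: DomainGrid, values: Sequence[float] | np.ndarray):
        vals = np.asarray(values, dtype=float)
        if vals.shape != (grid.length,):
            raise GridError(
                f"values shape {vals.shape} does not match grid length {grid.length}"
            )
        if not np.all(np.isfinite(vals)):
            raise FormatError("curve values must be finite")
        vals.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", vals)

    def __add__(self, other: "Curve") -> "Curve":
        self._check_shared_grid(other)
        return Curve(self.grid, self.values + other.values)

    def __sub__(self, other: "Curve") -> "Curve":
        self._check_shared_grid(other)
        return Curve(self.grid, self.values - other.values)

    def _check_shared_grid(self, other: "Curve") -> None:
        if self.grid != other.grid:
            raise GridError("curves are not on a shared grid")


@dataclass(frozen=True)
class MeanFunctionPair:
    """Population mean functions of the two groups and their difference."""

    mu1: Curve
    mu2: Curve
    difference: Curve = field(init=False)

    def __post_init__(self):
        if self.mu1.grid != self.mu2.grid:
            raise GridError("mu1 and mu2 must share one grid")
        object.__setattr__(self, "difference", self.mu1 - self.mu2)

    @property
    def grid(self) -> DomainGrid:
        return self.mu1.grid

    def as_null(self) -> "MeanFunctionPair":
        """The pair with both means equal to mu1 (identical-means null)."""
        return MeanFunctionPair(self.mu1, self.mu1)


def read_mean_pair(
    path, columns: tuple[str, str, str] = ("t", "mu1", "mu2")
) -> MeanFunctionPair:
    """Read a mean-function pair from a CSV with a grid column and two means."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{path} is missing column(s) {missing}")
    if len(frame) < 2:
        raise FormatError(f"{path} must contain at least 2 rows")
    sub = frame[list(columns)]
    if sub.isna().any().any():
        raise FormatError(f"{path} has missing or non-numeric entries")
    grid = DomainGrid(sub[columns[0]].to_numpy(dtype=float))
    mu1 = Curve(grid, sub[columns[1]].to_numpy(dtype=float))
    mu2 = Curve(grid, sub[columns[2]].to_numpy(dtype=float))
    return MeanFunctionPair(mu1, mu2)


def write_mean_pair(pair: MeanFunctionPair, path) -> None:
    """Write a mean pair as CSV columns t, mu1, mu2 at full float precision."""
    frame = pd.DataFrame(
        {
            "t": pair.grid.points,
            "mu1": pair.mu1.values,
            "mu2": pair.mu2.values,
        }
    )
    frame.to_csv(path, index=False)


def resample_to_grid(curve: Curve, grid: DomainGrid) -> Curve:
    """Linearly interpolate a curve onto a target grid within its span."""
    src = curve.grid.points
    if grid.points[0] < src[0] or grid.points[-1] > src[-1]:
        raise DomainError(
            f"target grid [{grid.points[0]}, {grid.points[-1]}] exceeds source "
            f"span [{src[0]}, {src[-1]}]"
        )
    return Curve(grid, np.interp(grid.points, src, curve.values))


# Fixed schema for simulation result tables (one row per study cell).
RESULT_COLUMNS = [
    "pattern",
    "method",
    "noise_sd",
    "noise_fwhm",
    "n",
    "power",
    "ci_low",
    "ci_high",
    "fwer",
    "censored",
]


def write_results(records: Iterable[dict], path) -> None:
    """Write result rows as CSV with the fixed schema and a header row.

    ``records`` is an iterable of mappings keyed by :data:`RESULT_COLUMNS`;
    missing keys are written as empty fields (the convention for censored
    sample sizes whose FWER cell is left blank).
    """
    rows = list(records)
    for row in rows:
        unknown = set(row) - set(RESULT_COLUMNS)
        if unknown:
            raise FormatError(f"unknown result field(s): {sorted(unknown)}")
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, index=False)


def read_results(path) -> list[dict]:
    """Read a results table back into a list of row mappings."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if list(frame.columns) != RESULT_COLUMNS:
        raise FormatError(
            f"{path} does not have the results schema {RESULT_COLUMNS}"
        )
    records = []
    for row in frame.to_dict(orient="records"):
        clean = {}
        for key, value in row.items():
            if isinstance(value, float) and np.isnan(value):
                continue
            if key == "censored":
                value = bool(value)
            elif key == "n":
                # censored sizes are serialised as ">cap" strings
                try:
                    value = int(value)
                except (TypeError, ValueError):
                    value = str(value)
            clean[key] = value
        records.append(clean)
    return records
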