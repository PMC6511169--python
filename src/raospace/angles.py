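"""Angle ingestion, normalization, and the Rao spacing statistic U.

Circular observations live on [0, 2pi) where 0 and 2pi coincide.  Rao's
spacing test measures departure from uniformity through the arc lengths
between neighbouring points: under perfect uniformity every arc equals
2pi/n, and the statistic

    U = 0.5 * sum_i |T_i - 2pi/n|

accumulates the absolute deviations from that expectation (the factor 0.5
avoids double counting, since the signed deviations sum to zero).  U = 0 at
exact equal spacing and U = 2pi(n-1)/n when all points coincide.

Everything internal is in radians; degrees appear only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

TWO_PI = 2.0 * math.pi

#: accepted raw-input windows; finite on purpose so unit mistakes
#: (degrees fed as radians, or vice versa) fail loudly instead of wrapping
_RADIAN_RANGE = (-4.0 * math.pi, 6.0 * math.pi)
_DEGREE_RANGE = (-720.0, 1080.0)


class AngleRangeError(ValueError):
    """A raw angle lies outside the accepted input range."""


class SampleSizeError(ValueError):
    """Fewer than two observations were supplied."""


@dataclass(frozen=True)
class AngleSample:
    """A validated circular sample: sorted radians on [0, 2pi).

    Ties are legal and preserved — rounded (grouped) data produces ties, and
    those ties are exactly what breaks the continuous-theory critical values.

    Attributes
    ----------
    values : np.ndarray
        Angles in radians, each in [0, 2pi), sorted ascending.
    source_unit : str
        ``"radians"`` or ``"degrees"``; provenance only, values are always
        stored in radians.
    """

    values: np.ndarray
    source_unit: str = "radians"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("angle values must be one-dimensional")
        if v.size < 2:
            raise SampleSizeError(
                f"need at least 2 observations, got {v.size}"
            )
        if np.any(v < 0.0) or np.any(v >= TWO_PI):
            raise ValueError("AngleSample values must lie in [0, 2pi)")
        if np.any(np.diff(v) < 0.0):
            raise ValueError("AngleSample values must be sorted ascending")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class SpacingSet:
    """The n circular arc lengths between neighbouring sample points.

    Arc i (i < n) is phi_{i+1} - phi_i; arc n wraps across 0/2pi as
    2pi - phi_n + phi_1.  The arcs are nonnegative and sum to 2pi.
    """

    arcs: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.arcs, dtype=float)
        object.__setattr__(self, "arcs", a)

    @property
    def n(self) -> int:
        return int(self.arcs.size)


@dataclass(frozen=True)
class RaoStatistic:
    """The Rao spacing statistic in both units.

    ``u_radians`` is bounded by 0 <= U <= 2pi(n-1)/n; the published critical
    values are tabulated in degrees, hence the dual representation.
    """

    u_radians: float
    u_degrees: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.u_degrees is None:
            object.__setattr__(self, "u_degrees", math.degrees(self.u_radians))


def normalize_angles(
    raw: Sequence[float], unit: str = "radians"
) -> AngleSample:
    """Validate, convert, and wrap raw angles into an :class:`AngleSample`.

    Parameters
    ----------
    raw : sequence of float
        Angles in ``unit``.  Radians must lie in [-4pi, 6pi); degrees in
        [-720, 1080).  The deliberately finite window catches unit mistakes
        (e.g. degrees passed as radians) instead of silently wrapping them.
    unit : {"radians", "degrees"}
        Unit of ``raw``.  Explicit by design: a value like 350 would be
        admissible in either unit, so autodetection is unsafe.
    """
    if unit not in ("radians", "degrees"):
        raise ValueError(f"unit must be 'radians' or 'degrees', got {unit!r}")
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input: no angles supplied")
    if np.any(~np.isfinite(arr)):
        raise ValueError("non-finite angle encountered")
    lo, hi = _RADIAN_RANGE if unit == "radians" else _DEGREE_RANGE
    bad = (arr < lo) | (arr >= hi)
    if np.any(bad):
        offender = float(arr[bad][0])
        raise AngleRangeError(
            f"angle {offender!r} outside accepted {unit} range [{lo}, {hi})"
        )
    if arr.size < 2:
        raise SampleSizeError(f"need at least 2 observations, got {arr.size}")
    if unit == "degrees":
        arr = np.radians(arr)
    arr = np.mod(arr, TWO_PI)
    # mod can return 2pi exactly for tiny negative inputs under roundoff
    arr[arr >= TWO_PI] = 0.0
    arr = np.sort(arr, kind="stable")
    return AngleSample(values=arr, source_unit=unit)


def spacings(sample: AngleSample) -> SpacingSet:
    """Arc lengths between neighbouring points, including the wrap-around arc."""
    v = sample.values
    arcs = np.empty(sample.n)
    arcs[:-1] = np.diff(v)
    arcs[-1] = TWO_PI - v[-1] + v[0]
    return SpacingSet(arcs=arcs)


def rao_u(sample: AngleSample) -> RaoStatistic:
    """Compute Rao's spacing statistic U = 0.5 * sum |T_i - 2pi/n|."""
    arcs = spacings(sample).arcs
    u = 0.5 * float(np.abs(arcs - TWO_PI / sample.n).sum())
    return RaoStatistic(u_radians=u)


def rao_u_rows(phi_sorted: np.ndarray) -> np.ndarray:
    """Vectorized U over a matrix of row-sorted samples (radians).

    Fast path shared by the randomization tests and the simulation study;
    each row must already be sorted and lie in [0, 2pi).
    """
    m, n = phi_sorted.shape
    expected = TWO_PI / n
    dev = np.abs(np.diff(phi_sorted, axis=1) - expected).sum(axis=1)
    wrap = TWO_PI - phi_sorted[:, -1] + phi_sorted[:, 0]
    return 0.5 * (dev + np.abs(wrap - expected))


def read_angles(
    path: Union[str, Path],
    unit: str = "radians",
    column: Union[str, int, None] = None,
) -> AngleSample:
    """Read angles from a plain-text file (one per line) or a CSV column.

    Parameters
    ----------
    path : path-like
        Input file.  Files ending in ``.csv`` (or when ``column`` is given)
        are parsed with pandas; otherwise one angle per line, blank lines
        and ``#`` comments ignored.
    unit : {"radians", "degrees"}
    column : str, int or None
        CSV column name or 0-based index.  ``None`` with a CSV takes the
        first column (header optional).
    """
    path = Path(path)
    if column is not None or path.suffix.lower() == ".csv":
        import pandas as pd

        if isinstance(column, str):
            df = pd.read_csv(path)
            if column not in df.columns:
                raise ValueError(
                    f"column {column!r} not found in {path} "
                    f"(have {list(df.columns)})"
                )
            series = df[column]
        else:
            idx = 0 if column is None else int(column)
            df = pd.read_csv(path, header=None)
            series = df.iloc[:, idx]
            try:
                series = series.astype(float)
            except (TypeError, ValueError):
                # first row was a header; drop it and retry
                series = series.iloc[1:].astype(float)
        vals = series.to_numpy(dtype=float)
        return normalize_angles(vals, unit=unit)

    vals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            try:
                vals.append(float(text))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: cannot parse angle from {text!r}"
                ) from exc
    return normalize_angles(vals, unit=unit)
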