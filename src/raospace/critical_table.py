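"""Traditional Rao spacing test via the published critical-value table.

The classical way to evaluate the test compares U (in degrees) against the
critical values tabulated by Russell & Levitin (1995) from the moments of
the spacing distribution.  The table covers every n from 4 to 30 and a
selection of larger sizes up to 1000, at significance levels 0.001, 0.01,
0.05 and 0.10; the same grid backs the widely used R implementation of the
test.  Because the table is finite in alpha, the traditional test reports
the p-value only as a bracket between adjacent tabulated levels.

This classical procedure assumes continuously measured angles.  On rounded
(grouped) data its type I error rate inflates badly with sample size — the
reason the simulation variants in :mod:`raospace.randomization` exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Tuple

import numpy as np

from .angles import AngleSample, RaoStatistic, rao_u

_TABLE_RESOURCE = "rao_critical_table.csv"


class UnsupportedSampleSizeError(ValueError):
    """Sample size outside the tabulated range 4..1000."""


class UnsupportedLevelError(ValueError):
    """Significance level not in the published table's alpha grid."""


class CriticalValueTable:
    """The Russell & Levitin n-by-alpha grid of U critical values (degrees).

    For tabulated n the cell value is returned exactly; for a non-tabulated
    n above 30 the critical value is interpolated linearly in n between the
    bracketing tabulated rows.
    """

    def __init__(self, sample_sizes: np.ndarray, alpha_levels: tuple,
                 values: np.ndarray):
        self.sample_sizes = np.asarray(sample_sizes, dtype=int)
        self.alpha_levels = tuple(float(a) for a in alpha_levels)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (self.sample_sizes.size, len(self.alpha_levels)):
            raise ValueError("table shape mismatch")

    @classmethod
    def load(cls) -> "CriticalValueTable":
        """Load the table shipped with the package."""
        import pandas as pd

        with resources.files(__package__).joinpath(
            "_data", _TABLE_RESOURCE
        ).open("r") as fh:
            df = pd.read_csv(fh, comment="#")
        alphas = tuple(float(c) for c in df.columns[1:])
        return cls(df.iloc[:, 0].to_numpy(int), alphas,
                   df.iloc[:, 1:].to_numpy(float))

    @property
    def n_min(self) -> int:
        return int(self.sample_sizes[0])

    @property
    def n_max(self) -> int:
        return int(self.sample_sizes[-1])

    def _alpha_index(self, alpha: float) -> int:
        for i, a in enumerate(self.alpha_levels):
            if abs(a - alpha) < 1e-12:
                return i
        raise UnsupportedLevelError(
            f"alpha={alpha} not in the published grid; "
            f"supported levels: {self.alpha_levels}"
        )

    def critical_value(self, n: int, alpha: float) -> float:
        """Critical value of U in degrees for sample size n at level alpha."""
        n = int(n)
        if n < self.n_min:
            raise UnsupportedSampleSizeError(
                f"n={n} below the tabulated minimum {self.n_min}"
            )
        if n > self.n_max:
            raise UnsupportedSampleSizeError(
                f"n={n} above the tabulated maximum {self.n_max}"
            )
        j = self._alpha_index(alpha)
        col = self.values[:, j]
        idx = np.searchsorted(self.sample_sizes, n)
        if self.sample_sizes[idx] == n:
            return float(col[idx])
        n0, n1 = self.sample_sizes[idx - 1], self.sample_sizes[idx]
        c0, c1 = col[idx - 1], col[idx]
        return float(c0 + (c1 - c0) * (n - n0) / (n1 - n0))


_DEFAULT_TABLE: CriticalValueTable | None = None


def get_table() -> CriticalValueTable:
    """The packaged table, loaded once and cached."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CriticalValueTable.load()
    return _DEFAULT_TABLE


def critical_value(n: int, alpha: float) -> float:
    """Critical value of U in degrees for the packaged table."""
    return get_table().critical_value(n, alpha)


@dataclass(frozen=True)
class TraditionalResult:
    """Outcome of the traditional (critical-value) Rao spacing test.

    ``p_bracket`` is the tightest interval for the p-value that the finite
    alpha grid supports: (0, 0.001) when U clears even the most stringent
    critical value, up to (0.10, 1) when it clears none.
    """

    statistic: RaoStatistic
    p_bracket: Tuple[float, float]
    reject: bool
    alpha: float
    n: int

    @property
    def method(self) -> str:
        return "traditional"


def traditional_test(sample: AngleSample, alpha: float = 0.05) -> TraditionalResult:
    """Run the traditional Rao spacing test against the published table.

    Rejects uniformity at level ``alpha`` iff U (degrees) exceeds the
    tabulated critical value.  Rejection is monotone in alpha because the
    critical values decrease as alpha increases.
    """
    table = get_table()
    stat = rao_u(sample)
    u_deg = stat.u_degrees
    # reject set across the grid: rejection at a small alpha implies
    # rejection at every larger one
    grid = sorted(table.alpha_levels)
    exceeded = [a for a in grid if u_deg > table.critical_value(sample.n, a)]
    if exceeded:
        upper = min(exceeded)
        pos = grid.index(upper)
        lower = 0.0 if pos == 0 else grid[pos - 1]
    else:
        lower, upper = max(grid), 1.0
    reject = u_deg > table.critical_value(sample.n, alpha)
    return TraditionalResult(
        statistic=stat, p_bracket=(lower, upper), reject=reject,
        alpha=alpha, n=sample.n,
    )
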