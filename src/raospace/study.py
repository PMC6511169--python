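"""Monte-Carlo study of type I error and power for the test variants.

The harness estimates rejection rates of the traditional (critical-value)
and simulation-based Rao spacing tests over replicated synthetic datasets:
uniform data measures type I error, von Mises or wrapped skew-normal data
measures power, and optional rounding to a grid of equal bins emulates the
finite measurement precision that breaks the traditional test.

Conventions follow the original experimental design: type I error is the
fraction of replicates with p-value strictly below alpha, power the fraction
with p-value at or below alpha.  For the simulation tests p takes values on
the grid k/(N_R+1) so the distinction is real; for the traditional test both
reduce to U exceeding the critical value.

The default scale (2,000 replicates, N_R = 2,000) keeps a full grid run at
desk timescales; ``full_scale`` switches to the original 10,000/10,000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .angles import TWO_PI, AngleSample, rao_u_rows
from .circdist import SkewNormalParams, VonMisesParams
from .critical_table import critical_value
from .randomization import (
    CONTINUOUS,
    RandomizationConfig,
    _round_rows,
    test_continuous,
    test_discrete,
)

logger = logging.getLogger(__name__)

#: sample-size grid covering the sizes highlighted in the original study
DEFAULT_SAMPLE_SIZES = (10, 20, 30, 50, 100, 200, 500, 1000)

TRADITIONAL = "traditional"
SIMULATION = "simulation"

UNIFORM = "uniform"
VON_MISES = "von_mises"
SKEW_NORMAL = "skew_normal"

DistParams = Union[VonMisesParams, SkewNormalParams, None]


@dataclass(frozen=True)
class StudyConfig:
    """One experimental condition (or a sweep over sample sizes).

    ``distribution`` of "uniform" makes the run a type I error study
    (rejection rule p < alpha); anything else is a power study (p <= alpha).
    """

    test_variant: str = SIMULATION
    distribution: str = UNIFORM
    dist_params: DistParams = None
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES
    binning: Union[int, str] = CONTINUOUS
    replicates: int = 2_000
    alpha: float = 0.05
    n_resamples: int = 2_000
    kappa: float = 1000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.test_variant not in (TRADITIONAL, SIMULATION):
            raise ValueError(f"unknown test_variant {self.test_variant!r}")
        if self.distribution not in (UNIFORM, VON_MISES, SKEW_NORMAL):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.distribution == VON_MISES and self.dist_params is None:
            object.__setattr__(self, "dist_params", VonMisesParams())
        if self.distribution == SKEW_NORMAL and self.dist_params is None:
            object.__setattr__(self, "dist_params", SkewNormalParams())

    @property
    def is_null(self) -> bool:
        return self.distribution == UNIFORM

    def at_full_scale(self) -> "StudyConfig":
        """The original experiment's scale: 10,000 replicates, N_R = 10,000."""
        return replace(self, replicates=10_000, n_resamples=10_000)


@dataclass
class StudyResult:
    """Tidy rejection-rate table: one row per (variant, distribution, n)."""

    table: pd.DataFrame

    COLUMNS = (
        "test_variant", "distribution", "n", "binning", "replicates",
        "rejection_rate", "binomial_se",
    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, path=None, ax=None):
        """Quick-look plot of rejection rate vs sample size, one line per
        (variant, distribution, binning) condition."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for key, grp in self.table.groupby(
            ["test_variant", "distribution", "binning"]
        ):
            grp = grp.sort_values("n")
            ax.errorbar(grp["n"], grp["rejection_rate"],
                        yerr=grp["binomial_se"], marker="o",
                        label="/".join(str(k) for k in key))
        ax.set_xscale("log")
        ax.set_xlabel("sample size n")
        ax.set_ylabel("rejection rate")
        ax.axhline(0.05, ls="--", c="grey", lw=0.8)
        ax.legend(fontsize="small")
        if path is not None:
            ax.figure.savefig(path, dpi=120)
            plt.close(ax.figure)
        return ax


def _draw_matrix(distribution: str, params: DistParams, shape,
                 rng: np.random.Generator) -> np.ndarray:
    """Replicates-by-n matrix of raw draws on [0, 2pi), unsorted."""
    if distribution == UNIFORM:
        return rng.uniform(0.0, TWO_PI, size=shape)
    if distribution == VON_MISES:
        p = params or VonMisesParams()
        if p.kappa == 0.0:
            x = rng.uniform(0.0, TWO_PI, size=shape)
        else:
            x = rng.vonmises(p.mu, p.kappa, size=shape)
    else:
        p = params or SkewNormalParams()
        delta = p.alpha_shape / math.sqrt(1.0 + p.alpha_shape ** 2)
        z0 = rng.standard_normal(shape)
        z1 = rng.standard_normal(shape)
        x = p.epsilon + p.omega * (
            delta * np.abs(z0) + math.sqrt(1.0 - delta ** 2) * z1
        )
    x = np.mod(x, TWO_PI)
    x[x >= TWO_PI] = 0.0
    return x


def _traditional_rate(config: StudyConfig, n: int,
                      rng: np.random.Generator) -> float:
    """Vectorized rejection rate of the critical-value test."""
    crit_deg = critical_value(n, config.alpha)
    crit_rad = math.radians(crit_deg)
    rejected = 0
    remaining = config.replicates
    max_rows = max(1, 4_000_000 // n)
    while remaining > 0:
        rows = min(max_rows, remaining)
        phi = _draw_matrix(config.distribution, config.dist_params,
                           (rows, n), rng)
        if config.binning != CONTINUOUS:
            phi = _round_rows(phi, int(config.binning))
        phi.sort(axis=1)
        u = rao_u_rows(phi)
        rejected += int((u > crit_rad).sum())
        remaining -= rows
    return rejected / config.replicates


def _simulation_rate(config: StudyConfig, n: int,
                     seed_seq: np.random.SeedSequence) -> float:
    """Rejection rate of the simulation-based test, one test per replicate."""
    children = seed_seq.spawn(config.replicates)
    rejected = 0
    discrete = config.binning != CONTINUOUS
    for child in children:
        draw_seed, test_seed = child.spawn(2)
        rng = np.random.Generator(np.random.PCG64(draw_seed))
        phi = _draw_matrix(config.distribution, config.dist_params,
                           n, rng)
        if discrete:
            phi = _round_rows(phi, int(config.binning))
        phi.sort()
        sample = AngleSample(values=phi)
        rc = RandomizationConfig(
            n_resamples=config.n_resamples, kappa=config.kappa,
            seed=test_seed,
            n_bins=int(config.binning) if discrete else CONTINUOUS,
        )
        result = (test_discrete(sample, rc) if discrete
                  else test_continuous(sample, rc))
        if config.is_null:
            rejected += result.p_value < config.alpha
        else:
            rejected += result.p_value <= config.alpha
    return rejected / config.replicates


def rejection_rate(config: StudyConfig) -> StudyResult:
    """Estimate rejection rates for one condition across its sample sizes.

    Under uniform data the rate estimates the type I error; under a
    non-uniform alternative it estimates power.  Seeded and reproducible.
    """
    root = np.random.SeedSequence(config.seed)
    per_n = root.spawn(len(list(config.sample_sizes)))
    rows = []
    for n, ss in zip(config.sample_sizes, per_n):
        if config.test_variant == TRADITIONAL:
            rng = np.random.Generator(np.random.PCG64(ss))
            rate = _traditional_rate(config, int(n), rng)
        else:
            rate = _simulation_rate(config, int(n), ss)
        se = math.sqrt(rate * (1.0 - rate) / config.replicates)
        rows.append({
            "test_variant": config.test_variant,
            "distribution": config.distribution,
            "n": int(n),
            "binning": config.binning,
            "replicates": config.replicates,
            "rejection_rate": rate,
            "binomial_se": se,
        })
    return StudyResult(pd.DataFrame(rows, columns=list(StudyResult.COLUMNS)))


def run_grid(configs: List[StudyConfig]) -> StudyResult:
    """Run a list of conditions, concatenating rows; failures are logged
    and skipped so one bad condition does not abort the grid."""
    if not configs:
        raise ValueError("empty study grid")
    frames = []
    for cfg in configs:
        try:
            frames.append(rejection_rate(cfg).table)
        except Exception:
            logger.exception("study condition failed: %r", cfg)
    if not frames:
        raise RuntimeError("every study condition failed")
    return StudyResult(pd.concat(frames, ignore_index=True))


def figure_grid(
    seed: Optional[int] = None,
    replicates: int = 2_000,
    n_resamples: int = 2_000,
    sample_sizes: Sequence[int] = (10, 20, 30, 50, 100),
    full_scale: bool = False,
) -> List[StudyConfig]:
    """The six-panel study design: type I error and von Mises power for
    both variants, continuous and rounded to 360 and 36 bins."""
    base = StudyConfig(
        replicates=replicates, n_resamples=n_resamples,
        sample_sizes=tuple(sample_sizes), seed=seed,
    )
    if full_scale:
        base = base.at_full_scale()
    grid = []
    seed_seq = np.random.SeedSequence(seed)
    offsets = seed_seq.generate_state(12).tolist()
    i = 0
    for binning in (CONTINUOUS, 360, 36):
        for distribution in (UNIFORM, VON_MISES):
            for variant in (TRADITIONAL, SIMULATION):
                if variant == TRADITIONAL and binning != CONTINUOUS \
                        and distribution != UNIFORM:
                    # the original design drops the traditional test for
                    # rounded power panels; keep type-I inflation panels
                    continue
                grid.append(replace(
                    base, test_variant=variant, distribution=distribution,
                    binning=binning,
                    seed=None if seed is None else int(offsets[i % 12]),
                ))
                i += 1
    return grid
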