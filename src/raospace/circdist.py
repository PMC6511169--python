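"""Seedable circular random samplers.

Three generators cover the distributions the simulation study needs: the
circular uniform (the null), the von Mises (the canonical unimodal circular
alternative, with mean direction mu and concentration kappa), and a wrapped
skew-normal (an asymmetric alternative: linear skew-normal draws wrapped
onto the circle).  All samplers return sorted :class:`~raospace.angles.AngleSample`
objects with values strictly inside [0, 2pi) and are deterministic under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .angles import TWO_PI, AngleSample, SampleSizeError

RngLike = Union[np.random.Generator, int, None]


def _as_generator(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class VonMisesParams:
    """Mean direction mu (radians, [0, 2pi)) and concentration kappa >= 0.

    kappa = 0 reduces to the circular uniform; large kappa approaches a
    normal with standard deviation ~ 1/sqrt(kappa).
    """

    mu: float = math.pi
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


@dataclass(frozen=True)
class SkewNormalParams:
    """Location epsilon, shape alpha, scale omega (radians) of a skew normal.

    Standard location/scale/shape convention: with delta = alpha/sqrt(1+alpha^2)
    a draw is X = epsilon + omega * (delta*|Z0| + sqrt(1-delta^2)*Z1) for
    independent standard normals Z0, Z1.  Draws are wrapped modulo 2pi, which
    with omega around 2 radians is consequential and deliberate.
    """

    epsilon: float = math.pi
    alpha_shape: float = 30.0
    omega: float = 2.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")


def _finish(values: np.ndarray) -> AngleSample:
    values = np.mod(values, TWO_PI)
    values[values >= TWO_PI] = 0.0
    values.sort()
    return AngleSample(values=values)


def runiform_circular(n: int, rng: RngLike = None) -> AngleSample:
    """n i.i.d. draws from the circular uniform on [0, 2pi)."""
    if n < 2:
        raise SampleSizeError(f"need at least 2 observations, got {n}")
    g = _as_generator(rng)
    return _finish(g.uniform(0.0, TWO_PI, size=n))


def rvonmises(
    n: int, params: VonMisesParams = VonMisesParams(), rng: RngLike = None
) -> AngleSample:
    """n i.i.d. von Mises(mu, kappa) draws on [0, 2pi).

    Uses the Best-Fisher rejection sampler (numpy's generator).  kappa = 0
    falls back to the circular uniform, which the rejection scheme does not
    cover.
    """
    if n < 2:
        raise SampleSizeError(f"need at least 2 observations, got {n}")
    g = _as_generator(rng)
    if params.kappa == 0.0:
        return _finish(g.uniform(0.0, TWO_PI, size=n))
    draws = g.vonmises(params.mu, params.kappa, size=n)
    return _finish(draws)


def rskewnormal_wrapped(
    n: int, params: SkewNormalParams = SkewNormalParams(), rng: RngLike = None
) -> AngleSample:
    """n i.i.d. skew-normal draws wrapped onto the circle.

    The two-normal representation keeps the sampler exact and trivially
    seedable; scipy's skewnorm is used as an independent oracle in the
    tests, never here.
    """
    if n < 2:
        raise SampleSizeError(f"need at least 2 observations, got {n}")
    g = _as_generator(rng)
    a = params.alpha_shape
    delta = a / math.sqrt(1.0 + a * a)
    z0 = g.standard_normal(n)
    z1 = g.standard_normal(n)
    x = params.epsilon + params.omega * (
        delta * np.abs(z0) + math.sqrt(1.0 - delta * delta) * z1
    )
    return _finish(x)
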