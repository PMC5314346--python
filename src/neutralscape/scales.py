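"""Range-size law, correlation length, and physical-unit conversion.

The model's unit of length is delta = sqrt(A / J), the typical spacing
between neighbouring individuals, so a landscape of area A holding J
individuals has area J in natural units.  A species of abundance m is the
descendant cloud of a single founder whose *spatial* effective age is m
generations (intraspecific replacements do not move the cloud), each birth
displacing by ~sigma; its expected squared range is therefore

    xi^2(m, sigma) = c1 sigma^2 m        (natural units, c1 ~ 1)

and the value of xi for the most abundant species (abundance scale M) is
the correlation length of the community.  Because M(nu, sigma) solves a
transcendental equation, xi(nu) is *not* a simple power law in nu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InterfaceLaw, ModelParams
from .theory import abundance_cutoff

__all__ = [
    "Landscape",
    "RangeConstraint",
    "range_size",
    "sigma_interval_from_constraints",
    "correlation_length",
]


@dataclass(frozen=True)
class Landscape:
    """A physical landscape: total area and number of individuals."""

    area_km2: float
    J: float

    def __post_init__(self) -> None:
        if self.area_km2 <= 0 or self.J < 1:
            raise ValueError("area and J must be positive")

    @property
    def delta_m(self) -> float:
        """Natural length unit sqrt(A/J) in meters."""
        return math.sqrt(self.area_km2 * 1e6 / self.J)

    def to_natural(self, length_m: float) -> float:
        return length_m / self.delta_m

    def to_meters(self, length_natural: float) -> float:
        return length_natural * self.delta_m


@dataclass(frozen=True)
class RangeConstraint:
    """One species' observed (abundance, occupied fraction of the landscape)."""

    abundance: float
    occupancy_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.occupancy_fraction <= 1:
            raise ValueError("occupancy_fraction must be in (0, 1]")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


def range_size(m: float, sigma: float, c1: float = 1.0) -> float:
    """Expected squared range xi^2 = c1 sigma^2 m in natural units."""
    if m < 1:
        raise ValueError("abundance must be >= 1")
    if sigma < 1:
        raise ValueError("sigma must be >= 1")
    if not 0 < c1:
        raise ValueError("c1 must be positive")
    return c1 * sigma**2 * m


def sigma_for_constraint(con: RangeConstraint, landscape: Landscape, c1: float = 1.0) -> float:
    """Invert the range law: sigma with xi^2 = occupancy_fraction * J."""
    xi2 = con.occupancy_fraction * landscape.J  # landscape area in natural units is J
    return math.sqrt(xi2 / (c1 * con.abundance))


def sigma_interval_from_constraints(
    constraints: list[RangeConstraint],
    landscape: Landscape,
    c1: float = 1.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Admissible [sigma_min, sigma_max] in natural units and in meters.

    Each constraint pins one sigma; the interval spans the pinned values.
    (With one constraint the interval is degenerate.)
    """
    if not constraints:
        raise ValueError("at least one constraint required")
    sig = sorted(sigma_for_constraint(c, landscape, c1) for c in constraints)
    nat = (sig[0], sig[-1])
    meters = (landscape.to_meters(nat[0]), landscape.to_meters(nat[1]))
    return nat, meters


def correlation_length(
    params: ModelParams, law: InterfaceLaw | None = None, c1: float = 1.0
) -> float:
    """Correlation length xi = sqrt(c1 sigma^2 M(nu, sigma)) in natural units.

    Beyond this scale community composition is uncorrelated.  Note the
    nu-dependence enters through M, the solution of a transcendental
    equation, so log xi is not linear in log nu.
    """
    M = abundance_cutoff(params, law)
    return float(np.sqrt(range_size(max(M, 1.0), params.sigma, c1)))
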