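"""Parameter containers for the spatial neutral community model.

The model describes ``J`` individuals on a landscape undergoing zero-sum
birth-death dynamics: in each elementary event one individual dies and the
vacancy is filled by the offspring of another individual, drawn from a
recruitment kernel of width ``sigma``.  With probability ``nu`` the newborn
founds a new species.  Lengths are measured in units of the mean
inter-individual spacing, so ``sigma >= 1`` (at ``sigma = 1`` recruitment is
from nearest neighbours, the smallest displacement a lattice allows).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["ModelParams", "InterfaceLaw", "SmallNuWarning"]


class SmallNuWarning(UserWarning):
    """The analytic theory is derived for small speciation rates."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the neutral birth-death-speciation process.

    Parameters
    ----------
    J:
        Total community size (number of individuals).
    nu:
        Speciation probability per birth, ``0 < nu <= 1``.
    sigma:
        Recruitment-kernel width: the root mean squared parent-offspring
        displacement, in units of the inter-individual spacing.  ``sigma = 1``
        is nearest-neighbour recruitment; ``math.inf`` is the well-mixed
        limit.
    eta:
        Generation-overlap constant: 1 for a Moran process (overlapping
        generations), 2 for Wright-Fisher.
    """

    J: float
    nu: float
    sigma: float = math.inf
    eta: int = 1

    def __post_init__(self) -> None:
        if not self.J >= 1:
            raise ValueError(f"J must be >= 1, got {self.J}")
        if not 0 < self.nu <= 1:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        if not self.sigma >= 1:
            raise ValueError(f"sigma must be >= 1, got {self.sigma}")
        if self.eta not in (1, 2):
            raise ValueError(f"eta must be 1 (Moran) or 2 (Wright-Fisher), got {self.eta}")
        if 0.1 < self.nu < 1:  # nu = 1 is an exact degenerate case
            warnings.warn(
                f"nu = {self.nu} is large; the analytic theory is accurate for small nu",
                SmallNuWarning,
                stacklevel=3,
            )

    @property
    def theta(self) -> float:
        """Fundamental biodiversity number, eta * nu * J / (1 - nu).

        Equals Fisher's alpha, the expected number of singleton species in
        the well-mixed limit.
        """
        if self.nu == 1:
            return math.inf
        return self.eta * self.nu * self.J / (1.0 - self.nu)

    @property
    def nu_prime(self) -> float:
        """Decay rate of the Fisher log-series, -ln(1 - nu)."""
        if self.nu == 1:
            return math.inf
        return -math.log1p(-self.nu)


@dataclass(frozen=True)
class InterfaceLaw:
    """The interface-correction coefficient c as a function of sigma.

    Spatial clustering reduces the chance that a birth-death event is
    interspecific.  The reduction enters the species abundance distribution
    through a single coefficient ``c = 1 / (a (sigma^2 - 1) + b)``, which
    decreases to zero in the well-mixed limit (``sigma -> inf``) where
    Fisher's log-series is recovered.  The default constants are the
    simulation-calibrated values ``a = 3.22``, ``b = 2.58``.
    """

    a: float = 3.22
    b: float = 2.58

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("interface-law constants a, b must be positive")

    def c(self, sigma: float) -> float:
        """Evaluate c(sigma); requires sigma >= 1."""
        if not sigma >= 1:
            raise ValueError(f"sigma must be >= 1, got {sigma}")
        if math.isinf(sigma):
            return 0.0
        return 1.0 / (self.a * (sigma**2 - 1.0) + self.b)

    def sigma_of_c(self, c: float) -> float:
        """Inverse of :meth:`c` (used when fitting simulated data)."""
        if not 0 < c <= 1.0 / self.b:
            raise ValueError(f"c must be in (0, 1/b], got {c}")
        return math.sqrt((1.0 / c - self.b) / self.a + 1.0)
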