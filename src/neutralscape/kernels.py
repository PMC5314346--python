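"""Discretized recruitment kernel shared by the forward and backward simulators.

The model's ``sigma`` is the root mean squared parent-offspring displacement
in lattice units.  The kernel assigns to every nonzero integer displacement
``d`` within a truncation radius a Gaussian weight ``exp(-|d|^2 / (2 s^2))``,
with the internal scale ``s`` calibrated so that the *realized* mean squared
displacement of the discrete, truncated kernel equals ``sigma^2`` exactly.
As ``sigma -> 1`` the weights concentrate on the four nearest neighbours
(|d| = 1 is the smallest displacement a lattice admits, which is why the
model requires sigma >= 1).  The focal site itself (d = 0) is excluded: the
vacancy is filled by the offspring of *another* individual.

On small tori the truncation radius can exceed half the lattice; displacement
weights are then folded onto their minimal-image classes, so ``sigma >> L``
smoothly approaches uniform (well-mixed) recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = ["RecruitmentKernel", "build_kernel"]


@dataclass(frozen=True)
class RecruitmentKernel:
    """Tabulated displacement distribution: (dx, dy) with cumulative weights."""

    sigma: float
    dx: np.ndarray
    dy: np.ndarray
    weights: np.ndarray  # normalized
    cum_weights: np.ndarray

    @property
    def mean_squared_displacement(self) -> float:
        return float(np.sum(self.weights * (self.dx**2 + self.dy**2)))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        k = np.searchsorted(self.cum_weights, rng.random(size))
        return self.dx[k], self.dy[k]


def _raw_weights(s: float, radius: int):
    d = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(d, d, indexing="ij")
    r2 = (dx**2 + dy**2).astype(float)
    valid = (r2 > 0) & (r2 <= radius**2)
    # shift by the minimum r^2 = 1 so tiny s does not underflow
    w = np.zeros_like(r2)
    w[valid] = np.exp(-(r2[valid] - 1.0) / (2.0 * s**2))
    return dx, dy, r2, w


def _msd(s: float) -> float:
    radius = max(2, int(np.ceil(4.0 * s)))
    _, _, r2, w = _raw_weights(s, radius)
    return float(np.sum(w * r2) / np.sum(w))


def build_kernel(sigma: float, L: int | None = None) -> RecruitmentKernel:
    """Build the recruitment kernel for width ``sigma`` (>= 1).

    If ``L`` is given the kernel is folded onto minimal-image displacement
    classes of an ``L x L`` torus (required whenever the truncation radius
    is not small compared to ``L``).
    """
    if not sigma >= 1:
        raise ValueError(f"sigma must be >= 1, got {sigma}")
    if L is not None and sigma >= 2 * L:
        # a kernel much wider than the torus is uniform over all other sites
        d = np.arange(L) - L // 2
        dx, dy = np.meshgrid(d, d, indexing="ij")
        keep = (dx != 0) | (dy != 0)
        dx = dx[keep].astype(np.int64).ravel()
        dy = dy[keep].astype(np.int64).ravel()
        w = np.full(dx.size, 1.0 / dx.size)
        order = np.lexsort((dy, dx))
        dx, dy, w = dx[order], dy[order], w[order]
        return RecruitmentKernel(sigma, dx, dy, w, np.cumsum(w))
    if sigma == 1.0:
        dx = np.array([1, -1, 0, 0], dtype=np.int64)
        dy = np.array([0, 0, 1, -1], dtype=np.int64)
        w = np.full(4, 0.25)
    else:
        # calibrate the internal Gaussian scale to the requested msd
        lo, hi = 1e-2, 4.0 * sigma
        while _msd(hi) < sigma**2:
            hi *= 2.0
        s = brentq(lambda t: _msd(t) - sigma**2, lo, hi, rtol=1e-12)
        radius = max(2, int(np.ceil(4.0 * s)))
        dxg, dyg, _, wg = _raw_weights(s, radius)
        keep = wg.ravel() > 0
        dx = dxg.ravel()[keep].astype(np.int64)
        dy = dyg.ravel()[keep].astype(np.int64)
        w = wg.ravel()[keep]
        w = w / w.sum()
    if L is not None:
        dx, dy, w = _fold_torus(dx, dy, w, L)
    order = np.lexsort((dy, dx))
    dx, dy, w = dx[order], dy[order], w[order]
    w = w / w.sum()
    return RecruitmentKernel(sigma, dx, dy, w, np.cumsum(w))


def _fold_torus(dx, dy, w, L):
    """Accumulate weights of displacements equivalent modulo L (excluding 0)."""
    fx = ((dx + L // 2) % L) - L // 2
    fy = ((dy + L // 2) % L) - L // 2
    key = (fx + L) * (2 * L + 1) + (fy + L)
    uniq, inv = np.unique(key, return_inverse=True)
    wacc = np.bincount(inv, weights=w)
    ux = uniq // (2 * L + 1) - L
    uy = uniq % (2 * L + 1) - L
    keep = ~((ux == 0) & (uy == 0))
    return ux[keep].astype(np.int64), uy[keep].astype(np.int64), wacc[keep]
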