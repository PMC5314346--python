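"""Subsampling theory: the SAD and richness seen by a random census.

A random sample of ``R J`` individuals from a community with SAD ``n(m)``
has expected sample SAD

    n(s) = sum_m n(m) Binom(s; m, R),

i.e. each species' sampled abundance is binomially thinned.  Sampling is
treated as independent (binomial rather than hypergeometric), an
approximation that is excellent for the tiny sampling ratios this module is
designed for (R ~ 1e-6 in continental-scale censuses).  Species with s = 0
are unseen, so the sample richness is

    S = sum_{s>=1} n(s) = sum_m n(m) (1 - (1-R)^m),

the second form being exact and cheap.  For abundances above ``1e4`` the
binomial kernel is replaced by its Poisson(R m) limit, accurate to ~1e-6
there and numerically safe up to m ~ 1e10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import InterfaceLaw, ModelParams
from .sad import SADCurve
from .theory import spatial_sad

__all__ = ["SampleSpec", "sample_sad", "sample_richness", "expected_singletons"]

#: abundance above which the binomial thinning kernel switches to Poisson
POISSON_SWITCH_M = 10_000
#: the sample SAD is truncated once the missed mass is below this fraction of RJ
_MASS_TOL = 1e-9


@dataclass(frozen=True)
class SampleSpec:
    """A random census sampling a fraction ``R`` of the community."""

    R: float

    def __post_init__(self) -> None:
        if not 0 < self.R <= 1:
            raise ValueError(f"sampling ratio R must be in (0, 1], got {self.R}")

    def sample_size(self, J: float) -> float:
        return self.R * J


def _s_max(sad: SADCurve, R: float) -> int:
    """Sampled-abundance ceiling leaving < _MASS_TOL of the sampled mass."""
    lam_max = R * float(np.max(sad.m))
    # Poisson tail bound: lam + k sqrt(lam) + k with k covering 1e-9
    k = 8.0
    return int(np.ceil(lam_max + k * np.sqrt(lam_max) + k)) + 1


def sample_sad(sad: SADCurve, spec: SampleSpec) -> SADCurve:
    """Expected SAD of a binomially thinned sample (s >= 1 classes only)."""
    R = spec.R
    if R == 1.0:
        return SADCurve(sad.m.copy(), sad.n.copy(), weights=sad.weights.copy(),
                        M=sad.M, meta=dict(sad.meta))
    s_hi = _s_max(sad, R)
    s = np.arange(1, s_hi + 1, dtype=float)
    wn = sad.weights * sad.n
    small = sad.m <= POISSON_SWITCH_M
    n_s = np.zeros_like(s)
    if np.any(small):
        m_sm = sad.m[small]
        # the binomial block only reaches s values attainable from m <= switch
        lam_bin = R * float(m_sm.max())
        s_bin = min(s.size, int(np.ceil(lam_bin + 8 * np.sqrt(lam_bin) + 8)) + 1)
        block = max(1, int(2e7 // max(1, m_sm.size)))
        for lo in range(0, s_bin, block):
            sl = s[lo : min(lo + block, s_bin), None]
            pmf = stats.binom.pmf(sl, m_sm[None, :], R)
            n_s[lo : min(lo + block, s_bin)] = pmf @ wn[small]
    if np.any(~small):
        m_lg = sad.m[~small]
        lam = R * m_lg
        block = max(1, int(2e7 // max(1, m_lg.size)))
        for lo in range(0, s.size, block):
            sl = s[lo : lo + block, None]
            pmf = stats.poisson.pmf(sl, lam[None, :])
            n_s[lo : lo + block] += pmf @ wn[~small]
    return SADCurve(s, n_s, M=(R * sad.M if sad.M else None),
                    meta={**sad.meta, "R": R})


def sample_richness(
    params: ModelParams,
    law: InterfaceLaw | None = None,
    spec: SampleSpec | None = None,
    *,
    sad: SADCurve | None = None,
) -> float:
    """Expected species richness S(nu, sigma) of a sample of R J individuals.

    Computed from the closed form ``sum_m n(m) (1 - (1-R)^m)``; a
    pre-computed metacommunity ``sad`` may be supplied to avoid rebuilding
    it (as in contour root-finding).
    """
    if spec is None:
        raise ValueError("a SampleSpec is required")
    if sad is None:
        sad = spatial_sad(params, law)
    seen = -np.expm1(sad.m * np.log1p(-spec.R)) if spec.R < 1 else np.ones_like(sad.m)
    return float(np.sum(sad.weights * sad.n * seen))


def expected_singletons(sad: SADCurve) -> float:
    """n(1): expected number of species observed exactly once."""
    return sad.singletons
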