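"""Fitting the analytic theory to simulated or empirical SADs.

SADs span many decades in abundance, so all fitting happens on
logarithmically binned curves (Pueyo representation): geometric bins,
species counts divided by the integer bin width to give a per-abundance
density.  The interface coefficient c is fit per (J, nu, sigma) dataset by
least squares on log densities; the law c = 1/(a(sigma^2-1)+b) is then fit
across sigma by weighted linear regression of 1/c on sigma^2 - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _simcore
from .forward import CommunityState
from .params import InterfaceLaw, ModelParams
from .sad import SADCurve
from .theory import spatial_sad

__all__ = ["BinnedSAD", "log_bin", "fit_c", "fit_ab", "measure_interface",
           "CFit", "ABFit"]


@dataclass
class BinnedSAD:
    """Geometrically binned SAD: per-abundance densities with errors."""

    bin_edges: np.ndarray   # length nbins+1, geometric
    centers: np.ndarray     # geometric mid-points of populated bins
    density: np.ndarray     # species per unit abundance in each populated bin
    counts: np.ndarray      # raw species counts per populated bin
    se: np.ndarray          # standard error of density (0 if unknown)
    populated: np.ndarray = None  # mask over bins (aligned with bin_edges[:-1])

    @property
    def total_species(self) -> float:
        """sum(density * integer width) = total species count (conserved)."""
        return float(np.sum(self.counts))


def _int_width(lo: float, hi: float) -> float:
    """Number of integers in [lo, hi)."""
    return np.floor(hi - 1e-9) - np.ceil(lo) + 1.0


def log_bin(sad: SADCurve, ratio: float = 2.0) -> BinnedSAD:
    """Bin an empirical (integer-abundance) SAD into geometric bins."""
    if ratio <= 1:
        raise ValueError("bin ratio must be > 1")
    if sad.m.size == 0 or np.sum(sad.n) == 0:
        raise ValueError("empty SAD")
    m_max = float(sad.m.max())
    n_bins = int(np.floor(np.log(m_max) / np.log(ratio))) + 1
    edges = ratio ** np.arange(0.0, n_bins + 1.0)
    se = np.asarray(sad.meta.get("se", np.zeros_like(sad.n)))
    centers, dens, counts, dens_se, pop = [], [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (sad.m >= lo) & (sad.m < hi)
        pop.append(bool(np.any(sel)))
        if not pop[-1]:
            continue
        width = _int_width(lo, hi)
        centers.append(np.sqrt(lo * hi))
        counts.append(float(np.sum(sad.n[sel])))
        dens.append(counts[-1] / width)
        dens_se.append(float(np.sqrt(np.sum(se[sel] ** 2))) / width)
    return BinnedSAD(edges, np.array(centers), np.array(dens),
                     np.array(counts), np.array(dens_se), np.array(pop))


@dataclass
class CFit:
    c: float
    ci: tuple[float, float]
    c_boot: np.ndarray = field(repr=False, default=None)
    n_bins_used: int = 0


def binned_theory_density(binned: BinnedSAD, params: ModelParams,
                          c: float) -> np.ndarray:
    """Analytic per-abundance density averaged over the integers in each bin.

    Evaluating the continuous n(m) at geometric bin centers biases narrow
    bins (n(m) ~ 1/m varies within a bin), so the theory is binned exactly
    like the data.
    """
    from .theory import _log_density

    th = spatial_sad(params, c=c)
    A = th.meta["A"]
    edges = binned.bin_edges
    pop = (binned.populated if binned.populated is not None
           else np.ones(len(edges) - 1, dtype=bool))
    out = []
    for lo, hi, keep in zip(edges[:-1], edges[1:], pop):
        if not keep:
            continue
        lo_i, hi_i = int(np.ceil(lo)), int(np.floor(hi - 1e-9))
        m = np.arange(lo_i, hi_i + 1, dtype=float)
        dens = A * np.exp(_log_density(m, params, c)).sum() / len(m)
        out.append(dens)
    return np.array(out)


def _fit_c_once(binned: BinnedSAD, params: ModelParams, min_count: float,
                c_max: float = 2.0) -> tuple[float, int]:
    sel = binned.counts >= min_count
    if sel.sum() < 2:
        raise RuntimeError("too few populated bins to fit c")
    dens = binned.density[sel]

    def loss(c):
        ln_th = np.log(binned_theory_density(binned, params, c)[sel])
        return float(np.sum((np.log(dens) - ln_th) ** 2))

    res = minimize_scalar(loss, bounds=(1e-6, c_max), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"c fit did not converge: {res}")
    return float(res.x), int(sel.sum())


def fit_c(
    replicates: list[SADCurve],
    params: ModelParams,
    *,
    ratio: float = 2.0,
    min_count: float = 5.0,
    n_boot: int = 200,
    seed: int = 0,
) -> CFit:
    """Estimate the interface coefficient c from replicate empirical SADs.

    Bins with fewer than ``min_count`` species are excluded (small-count
    noise); the confidence interval is a percentile bootstrap over
    replicates.
    """
    if not replicates:
        raise ValueError("need at least one replicate SAD")
    pooled = _pool(replicates)
    c_hat, nb = _fit_c_once(log_bin(pooled, ratio), params, min_count)
    rng = np.random.default_rng(seed)
    boots = []
    if len(replicates) > 1 and n_boot > 0:
        for _ in range(n_boot):
            pick = rng.integers(0, len(replicates), len(replicates))
            try:
                cb, _ = _fit_c_once(
                    log_bin(_pool([replicates[i] for i in pick]), ratio),
                    params, min_count)
                boots.append(cb)
            except RuntimeError:
                continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = c_hat
    return CFit(c_hat, (float(lo), float(hi)), np.array(boots), nb)


def _pool(reps: list[SADCurve]) -> SADCurve:
    """Average replicate SADs onto a common integer abundance axis."""
    acc: dict[float, float] = {}
    for r in reps:
        for m, n in zip(r.m, r.n):
            acc[m] = acc.get(m, 0.0) + n / len(reps)
    ms = np.array(sorted(acc))
    return SADCurve(ms, np.array([acc[m] for m in ms]))


@dataclass
class ABFit:
    a: float
    b: float
    cov: np.ndarray
    se: tuple[float, float]

    def joint_chi2(self, a0: float, b0: float) -> float:
        """Mahalanobis distance^2 of (a0, b0) from the fit."""
        d = np.array([self.a - a0, self.b - b0])
        return float(d @ np.linalg.solve(self.cov, d))


def fit_ab(c_estimates: list[tuple[float, float]] | list[tuple[float, float, float]]) -> ABFit:
    """Fit c = 1/(a (sigma^2-1) + b) from (sigma, c[, se_c]) estimates.

    Weighted least squares of y = 1/c on x = sigma^2 - 1; weights from the
    propagated standard errors when given, else uniform.  At least three
    distinct sigma values are required.
    """
    rows = [tuple(map(float, t)) for t in c_estimates]
    if len({r[0] for r in rows}) < 3:
        raise ValueError("need c estimates at >= 3 distinct sigma values")
    x = np.array([r[0] ** 2 - 1.0 for r in rows])
    c = np.array([r[1] for r in rows])
    y = 1.0 / c
    if len(rows[0]) > 2 and all(len(r) > 2 and r[2] > 0 for r in rows):
        se_y = np.array([r[2] for r in rows]) / c**2  # d(1/c) = dc / c^2
        w = 1.0 / se_y**2
    else:
        w = np.ones_like(y)
    X = np.column_stack([x, np.ones_like(x)])
    WX = X * w[:, None]
    cov_unscaled = np.linalg.inv(X.T @ WX)
    beta = cov_unscaled @ (WX.T @ y)
    resid = y - X @ beta
    dof = max(len(y) - 2, 1)
    scale = float(resid @ (w * resid)) / dof
    # do not let a lucky noiseless fit report zero uncertainty
    cov = cov_unscaled * max(scale, np.finfo(float).tiny)
    return ABFit(float(beta[0]), float(beta[1]), cov,
                 (float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))))


def measure_interface(state: CommunityState, params: ModelParams) -> dict[int, float]:
    """Empirical interface function I(m) on a lattice snapshot.

    For each species, the summed kernel-weighted probability that the
    replacement of a conspecific death has a heterospecific parent; values
    lie in [0, m].  Returns mean I per abundance m.
    """
    from .kernels import build_kernel

    kern = state.kernel or build_kernel(params.sigma, L=state.L)
    q = _simcore.heterospecific_mass(state.labels, kern.dx, kern.dy, kern.weights)
    _, inv = np.unique(state.labels.ravel(), return_inverse=True)
    m_per = np.bincount(inv)
    i_per = np.bincount(inv, weights=q.ravel())
    out: dict[int, list[float]] = {}
    for m, I in zip(m_per, i_per):
        out.setdefault(int(m), []).append(float(I))
    return {m: float(np.mean(v)) for m, v in sorted(out.items())}
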