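"""Backward-in-time coalescence sampler.

Instead of running the forward dynamics to stationarity, only the ancestral
lineages of a sample are traced backward: each lineage jumps by the
recruitment kernel toward its parent, merges with a lineage it lands on
(shared parenthood), and terminates when the speciation event that founded
its species is reached (probability ``nu`` per birth).  The sample is then
partitioned into species exactly as in the stationary forward process, at a
cost that scales with the sample's ancestry rather than with equilibration
time - which is what makes very small speciation rates accessible.
"""

from __future__ import annotations

import numpy as np

from . import _simcore
from .kernels import build_kernel
from .params import ModelParams
from .sad import SADCurve

__all__ = ["sample_species", "sad_from_samples"]


def sample_species(
    params: ModelParams,
    sample_positions: np.ndarray | None = None,
    seed: int = 0,
    *,
    L: int | None = None,
    boundary: str = "torus",
) -> np.ndarray:
    """Species label for each sampled individual.

    Parameters
    ----------
    params:
        Model parameters; ``nu > 0`` is required (a zero speciation rate
        gives no termination guarantee).
    sample_positions:
        Integer array of shape (n, 2) of lattice coordinates.  Defaults to
        every site of the ``L x L`` torus.
    L:
        Torus side; defaults to ``sqrt(J)`` rounded.
    boundary:
        ``'torus'`` (periodic) or ``'unbounded'`` (lineages wander on the
        infinite plane; sample coordinates are then arbitrary integers).

    Returns
    -------
    Array of species ids, one per row of ``sample_positions``; equal ids
    mean conspecific individuals.
    """
    if not params.nu > 0:
        raise ValueError("nu must be positive for the backward sampler to terminate")
    if L is None:
        L = int(round(np.sqrt(params.J)))
    kern = build_kernel(params.sigma, L=L if boundary == "torus" else None)
    rng = np.random.default_rng(seed)
    sub_seed = int(rng.integers(0, 2**31 - 1))
    if sample_positions is None:
        if boundary != "torus":
            raise ValueError("explicit sample_positions required for unbounded mode")
        sites = np.arange(L * L, dtype=np.int64)
    else:
        sample_positions = np.asarray(sample_positions, dtype=np.int64)
        if boundary == "torus":
            sites = (sample_positions[:, 0] % L) * L + (sample_positions[:, 1] % L)
    if boundary == "torus":
        return _simcore.coalesce_torus(
            L, params.nu, kern.dx, kern.dy, kern.cum_weights, sites, sub_seed
        )
    if boundary != "unbounded":
        raise ValueError(f"unknown boundary {boundary!r}")
    return _simcore.coalesce_unbounded(
        params.nu, kern.dx, kern.dy, kern.cum_weights,
        np.ascontiguousarray(sample_positions[:, 0]),
        np.ascontiguousarray(sample_positions[:, 1]),
        sub_seed,
    )


def sad_from_samples(
    params: ModelParams,
    n_replicates: int,
    seed: int = 0,
    *,
    L: int | None = None,
    sample_positions: np.ndarray | None = None,
    boundary: str = "torus",
) -> SADCurve:
    """Mean empirical SAD over independent backward-sampled replicates.

    ``n[i]`` is the mean number of species of abundance ``m[i]`` per
    replicate; per-abundance standard errors over replicates are stored in
    ``meta['se']`` (aligned with ``m``).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    per_rep: list[dict[int, int]] = []
    for _ in range(n_replicates):
        lab = sample_species(
            params, sample_positions, int(rng.integers(0, 2**31 - 1)),
            L=L, boundary=boundary,
        )
        _, counts = np.unique(lab, return_counts=True)
        vals, reps = np.unique(counts, return_counts=True)
        per_rep.append(dict(zip(vals.tolist(), reps.tolist())))
    all_m = sorted({m for d in per_rep for m in d})
    mat = np.array([[d.get(m, 0) for m in all_m] for d in per_rep], dtype=float)
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(n_replicates) if n_replicates > 1 else np.zeros(len(all_m))
    sad = SADCurve(np.array(all_m, dtype=float), mean)
    sad.meta.update({
        "se": se,
        "n_replicates": n_replicates,
        "nu": params.nu,
        "sigma": params.sigma,
    })
    return sad
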