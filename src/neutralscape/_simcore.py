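"""Numba kernels for the lattice simulators.

Both simulators share the same discretized recruitment kernel (passed in as
displacement tables with cumulative weights); the backward sampler is the
time-reversed dual of the forward Moran process, which is what makes their
agreement a meaningful correctness check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from numba import njit, types
from numba.typed import Dict


@njit
def forward_events(labels, nu, dx, dy, cw, n_events, next_label, seed):
    """Run elementary birth-death events in place; returns next_label.

    Each event: a uniformly random individual dies; with probability nu the
    vacancy is filled by a newborn of a brand-new species, otherwise by the
    offspring of a kernel-displaced neighbour (minimal-image on the torus).
    """
    np.random.seed(seed)
    L = labels.shape[0]
    K = cw.shape[0]
    for _ in range(n_events):
        i = np.random.randint(0, L)
        j = np.random.randint(0, L)
        if np.random.random() < nu:
            labels[i, j] = next_label
            next_label += 1
        else:
            k = np.searchsorted(cw, np.random.random())
            if k >= K:
                k = K - 1
            labels[i, j] = labels[(i + dx[k]) % L, (j + dy[k]) % L]
    return next_label


@njit
def _find(parent, a):
    while parent[a] != a:
        parent[a] = parent[parent[a]]
        a = parent[a]
    return a


@njit
def coalesce_torus(L, nu, dx, dy, cw, sample_sites, seed):
    """Backward-in-time species assignment for lineages on an L x L torus.

    Ancestral lineages of the sampled individuals are traced backward: at
    each event one active lineage is picked uniformly (the time-reversed
    image of the uniform death rule); with probability nu the event was the
    speciation that founded the lineage's species (the lineage resolves),
    otherwise the lineage jumps to its parent's site, coalescing with any
    lineage already there.  Returns one species id per sampled individual.
    """
    np.random.seed(seed)
    n = sample_sites.shape[0]
    K = cw.shape[0]
    parent = np.arange(n)              # union-find over sample indices
    site_lineage = np.full(L * L, -1, dtype=np.int64)
    lin_site = np.empty(n, dtype=np.int64)
    act = np.empty(n, dtype=np.int64)  # compact list of active class reps
    n_active = 0
    species = np.full(n, -1, dtype=np.int64)
    for idx in range(n):
        s = sample_sites[idx]
        occ = site_lineage[s]
        if occ >= 0:
            parent[idx] = _find(parent, occ)  # same individual sampled twice
        else:
            site_lineage[s] = idx
            lin_site[idx] = s
            act[n_active] = idx
            n_active += 1
    next_sp = 0
    while n_active > 0:
        k = np.random.randint(0, n_active)
        lid = act[k]
        if np.random.random() < nu:
            species[_find(parent, lid)] = next_sp
            next_sp += 1
            site_lineage[lin_site[lid]] = -1
            act[k] = act[n_active - 1]
            n_active -= 1
        else:
            kk = np.searchsorted(cw, np.random.random())
            if kk >= K:
                kk = K - 1
            s = lin_site[lid]
            ns = ((s // L + dx[kk]) % L) * L + (s % L + dy[kk]) % L
            occ = site_lineage[ns]
            if occ >= 0:
                ra = _find(parent, lid)
                rb = _find(parent, occ)
                if ra != rb:
                    parent[ra] = rb
                site_lineage[s] = -1
                act[k] = act[n_active - 1]
                n_active -= 1
            else:
                site_lineage[s] = -1
                lin_site[lid] = ns
                site_lineage[ns] = lid
    out = np.empty(n, dtype=np.int64)
    for idx in range(n):
        out[idx] = species[_find(parent, idx)]
    return out


@njit
def coalesce_unbounded(nu, dx, dy, cw, sx, sy, seed):
    """Backward sampler on an unbounded plane (no wraparound).

    Site occupancy is tracked in a hash map keyed by packed coordinates, so
    lineages may wander arbitrarily far from the sample.
    """
    np.random.seed(seed)
    n = sx.shape[0]
    K = cw.shape[0]
    OFF = np.int64(1) << np.int64(31)
    parent = np.arange(n)
    occ_map = Dict.empty(key_type=types.int64, value_type=types.int64)
    lin_x = np.empty(n, dtype=np.int64)
    lin_y = np.empty(n, dtype=np.int64)
    act = np.empty(n, dtype=np.int64)
    n_active = 0
    species = np.full(n, -1, dtype=np.int64)
    for idx in range(n):
        key = (sx[idx] + OFF) * (OFF * 4) + (sy[idx] + OFF)
        if key in occ_map:
            parent[idx] = _find(parent, occ_map[key])
        else:
            occ_map[key] = idx
            lin_x[idx] = sx[idx]
            lin_y[idx] = sy[idx]
            act[n_active] = idx
            n_active += 1
    next_sp = 0
    while n_active > 0:
        k = np.random.randint(0, n_active)
        lid = act[k]
        old_key = (lin_x[lid] + OFF) * (OFF * 4) + (lin_y[lid] + OFF)
        if np.random.random() < nu:
            species[_find(parent, lid)] = next_sp
            next_sp += 1
            del occ_map[old_key]
            act[k] = act[n_active - 1]
            n_active -= 1
        else:
            kk = np.searchsorted(cw, np.random.random())
            if kk >= K:
                kk = K - 1
            nx = lin_x[lid] + dx[kk]
            ny = lin_y[lid] + dy[kk]
            key = (nx + OFF) * (OFF * 4) + (ny + OFF)
            if key in occ_map:
                ra = _find(parent, lid)
                rb = _find(parent, occ_map[key])
                if ra != rb:
                    parent[ra] = rb
                del occ_map[old_key]
                act[k] = act[n_active - 1]
                n_active -= 1
            else:
                del occ_map[old_key]
                occ_map[key] = lid
                lin_x[lid] = nx
                lin_y[lid] = ny
    out = np.empty(n, dtype=np.int64)
    for idx in range(n):
        out[idx] = species[_find(parent, idx)]
    return out


@njit
def heterospecific_mass(labels, dx, dy, w):
    """Per-site kernel-weighted probability of a heterospecific parent."""
    L = labels.shape[0]
    q = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            s = 0.0
            for k in range(dx.shape[0]):
                if labels[(i + dx[k]) % L, (j + dy[k]) % L] != labels[i, j]:
                    s += w[k]
            q[i, j] = s
    return q
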