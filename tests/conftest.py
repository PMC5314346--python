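"""Shared fixtures: expensive equilibrated ensembles are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import neutralscape as ns


@pytest.fixture(scope="session")
def forward_ensemble_64():
    """50 equilibrated forward runs at 64^2, nu=0.01, sigma=1.

    Returns a list of per-replicate species-abundance arrays.  Used by the
    forward/backward duality check and by tests that need stationary
    forward communities.
    """
    L, nu = 64, 0.01
    params = ns.ModelParams(J=L * L, nu=nu, sigma=1.0)
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(50):
        state = ns.init_community(L, "monodominant", int(rng.integers(2**31)))
        ns.run_to_equilibrium(state, params)
        out.append(state.species_abundances())
    return out


@pytest.fixture(scope="session")
def backward_ensemble_64():
    """50 backward-sampled stationary communities at 64^2, nu=0.01, sigma=1."""
    L, nu = 64, 0.01
    params = ns.ModelParams(J=L * L, nu=nu, sigma=1.0)
    rng = np.random.default_rng(777)
    out = []
    for _ in range(50):
        lab = ns.sample_species(params, seed=int(rng.integers(2**31)), L=L)
        out.append(np.unique(lab, return_counts=True)[1])
    return out
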