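"""Analytic SAD machinery: Fisher limit, spatial correction, richness."""

import math

import numpy as np
import pytest

import neutralscape as ns
from neutralscape import theory


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(J=0.5, nu=0.01), dict(J=100, nu=0.0), dict(J=100, nu=1.5),
         dict(J=100, nu=0.01, sigma=0.5), dict(J=100, nu=0.01, eta=3)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ns.ModelParams(**kw)

    def test_large_nu_warns(self):
        with pytest.warns(ns.SmallNuWarning):
            ns.ModelParams(J=100, nu=0.5)

    def test_theta_is_fishers_alpha(self):
        p = ns.ModelParams(J=1e6, nu=1e-3)
        assert p.theta == pytest.approx(1001.0, rel=1e-5)


class TestInterfaceLaw:
    def test_printed_constants_are_defaults(self):
        law = ns.InterfaceLaw()
        assert (law.a, law.b) == (3.22, 2.58)

    def test_nearest_neighbour_value(self):
        # sigma = 1: c = 1/b
        assert ns.c_of_sigma(1.0) == pytest.approx(1 / 2.58)

    def test_monotone_decreasing_to_zero(self):
        sig = np.array([1.0, 1.5, 2.0, 5.0, 50.0, 5e4])
        c = np.array([ns.c_of_sigma(s) for s in sig])
        assert np.all(np.diff(c) < 0)
        assert c[-1] < 1e-9
        assert ns.c_of_sigma(math.inf) == 0.0

    def test_sigma_below_one_rejected(self):
        with pytest.raises(ValueError):
            ns.c_of_sigma(0.9)


class TestFisher:
    def test_singletons_equal_theta(self):
        # J=1e6, nu=1e-3: n(1) = theta x ~= nu J, theta ~= 1001
        p = ns.ModelParams(J=1e6, nu=1e-3)
        sad = ns.fisher_sad(p)
        assert sad.singletons == pytest.approx(p.theta, rel=2e-3)

    def test_normalization_geometric_identity(self):
        for nu in (1e-2, 1e-4):
            p = ns.ModelParams(J=1e6, nu=nu)
            assert ns.fisher_sad(p).total_individuals == pytest.approx(1e6, rel=1e-6)

    def test_nu_one_degenerates_to_all_singletons(self):
        p = ns.ModelParams(J=500, nu=1.0)
        sad = ns.fisher_sad(p)
        assert sad.m.tolist() == [1.0]
        assert sad.n.tolist() == [500.0]
        assert ns.fisher_richness(p) == 500.0

    def test_richness_closed_form_matches_sum(self):
        p = ns.ModelParams(J=1e6, nu=1e-3)
        assert ns.fisher_richness(p) == pytest.approx(ns.fisher_sad(p).richness, rel=1e-6)

    def test_richness_monotone_in_nu(self):
        srs = [ns.fisher_richness(ns.ModelParams(J=1e6, nu=nu))
               for nu in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert np.all(np.diff(srs) > 0)


class TestSpatialSAD:
    def test_c_zero_equals_fisher_pointwise(self):
        p = ns.ModelParams(J=1e6, nu=1e-3)
        f, s = ns.fisher_sad(p), ns.spatial_sad(p, c=0.0)
        assert np.array_equal(f.m, s.m)
        assert np.max(np.abs(f.n - s.n)) == 0.0

    @pytest.mark.parametrize("J,nu,sigma", [(1e5, 1e-3, 1.0), (1e8, 1e-4, 2.0),
                                            (4.3e11, 1.3e-9, 3.0)])
    def test_normalization(self, J, nu, sigma):
        sad = ns.spatial_sad(ns.ModelParams(J=J, nu=nu, sigma=sigma))
        assert sad.total_individuals == pytest.approx(J, rel=1e-6)

    def test_nonnegative_and_nonincreasing(self):
        sad = ns.spatial_sad(ns.ModelParams(J=1e6, nu=1e-3, sigma=1.0))
        assert np.all(sad.n >= 0)
        assert np.all(np.diff(sad.n) <= 0)

    def test_quadrature_agrees_with_exact_integer_sum(self, monkeypatch):
        # force the log-grid path and compare with full integer summation
        p = ns.ModelParams(J=1e4, nu=1e-2, sigma=1.0)
        exact = ns.spatial_richness_exact(p)
        monkeypatch.setattr(theory, "EXACT_SUM_LIMIT", 100)
        quad = ns.spatial_richness_exact(p)
        assert quad == pytest.approx(exact, rel=1e-3)

    def test_cutoff_stored_and_below_fisher_scale(self):
        p = ns.ModelParams(J=1e8, nu=1e-4, sigma=1.0)
        sad = ns.spatial_sad(p)
        assert sad.M == pytest.approx(ns.abundance_cutoff(p))
        assert sad.M < 1.0 / p.nu  # clustering shortens the crossover


class TestSpatialRichness:
    def test_matches_fisher_when_c_zero(self):
        p = ns.ModelParams(J=1e6, nu=1e-3)
        assert ns.spatial_richness_exact(p, c=0.0) == pytest.approx(
            ns.fisher_richness(p), rel=1e-6)

    def test_decreasing_in_sigma(self):
        srs = [ns.spatial_richness_exact(ns.ModelParams(J=1e6, nu=1e-3, sigma=s))
               for s in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(srs) < 0)
        assert srs[-1] > ns.fisher_richness(ns.ModelParams(J=1e6, nu=1e-3))

    def test_approx_close_to_exact_spot_checks(self):
        for nu, sigma in [(1e-2, 1.0), (1e-4, 2.0), (1e-6, 5.0)]:
            p = ns.ModelParams(J=2.5e7, nu=nu, sigma=sigma)
            ex, ap = ns.spatial_richness_exact(p), ns.spatial_richness_approx(p)
            assert abs(ap - ex) / ex < 0.05

    def test_approx_decreasing_in_sigma(self):
        srs = [ns.spatial_richness_approx(ns.ModelParams(J=1e7, nu=1e-3, sigma=s))
               for s in np.linspace(1, 8, 10)]
        assert np.all(np.diff(srs) < 0)
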