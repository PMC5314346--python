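"""Calibration pipeline: contours, feasible region, bounds, predicted SAD."""

import numpy as np
import pytest

import neutralscape as ns
from neutralscape.amazon import CalibrationConfig


@pytest.fixture(scope="module")
def coarse_config():
    """Default constants on a coarse sigma grid (fast; bounds move < 1%)."""
    return CalibrationConfig(n_sigma_grid=12)


@pytest.fixture(scope="module")
def coarse_region(coarse_config):
    return ns.feasible_region(coarse_config)


class TestConfig:
    def test_sampling_ratio_reproduces_published_value(self):
        assert CalibrationConfig().R == pytest.approx(1.3e-6, rel=0.01)

    def test_from_dict_round_trip(self):
        cfg = CalibrationConfig.from_dict({
            "J": 1e9, "sample_size": 1e4,
            "constraints": [{"abundance": 1e6, "occupancy_fraction": 0.1}],
        })
        assert cfg.J == 1e9 and cfg.constraints[0].abundance == 1e6


class TestContours:
    def test_nu_increasing_in_sigma_along_contour(self, coarse_region):
        # larger sigma lowers richness, so nu must rise to compensate
        assert np.all(np.diff(coarse_region.nu_lo) > 0)
        assert np.all(np.diff(coarse_region.nu_hi) > 0)

    def test_corrected_contour_lies_above(self, coarse_region):
        assert np.all(coarse_region.nu_hi > coarse_region.nu_lo)

    def test_contour_stable_under_grid_refinement(self, coarse_config, coarse_region):
        fine = ns.feasible_region(CalibrationConfig(n_sigma_grid=24))
        interp = np.interp(coarse_region.sigma_grid, fine.sigma_grid, fine.nu_lo)
        assert np.max(np.abs(interp / coarse_region.nu_lo - 1)) < 0.005

    def test_full_sample_contour_reduces_to_metacommunity_richness(self):
        cfg = CalibrationConfig(J=1e6, sample_size=1e6,
                                observed_sample_richness=5000,
                                richness_correction_factor=1.0,
                                constraints=(), nu_bracket=(1e-9, 0.09))
        region = ns.feasible_region(cfg)
        nu = region.nu_lo[0]
        sr = ns.spatial_richness_exact(
            ns.ModelParams(J=1e6, nu=nu, sigma=region.sigma_grid[0]), cfg.law)
        assert sr == pytest.approx(5000, rel=1e-3)


class TestRegion:
    def test_sigma_interval_in_meters_matches_survey_scale(self, coarse_region):
        lo, hi = coarse_region.sigma_interval_m
        assert 10 < lo < hi < 25

    def test_no_constraints_degenerates_to_unbounded_band(self):
        cfg = CalibrationConfig(constraints=(), n_sigma_grid=4)
        region = ns.feasible_region(cfg)
        assert region.sigma_interval[1] == np.inf
        assert "unbounded" in region.note

    def test_correction_factor_one_collapses_band(self):
        cfg = CalibrationConfig(richness_correction_factor=1.0, n_sigma_grid=4)
        region = ns.feasible_region(cfg)
        assert np.array_equal(region.nu_lo, region.nu_hi)


class TestBounds:
    def test_bound_ordering_and_location(self, coarse_region, coarse_config):
        b = ns.metacommunity_bounds(coarse_region, coarse_config)
        assert b["SR_min"]["value"] <= b["SR_max"]["value"]
        assert b["singletons_min"]["value"] <= b["singletons_max"]["value"]
        s_lo, s_hi = coarse_region.sigma_interval
        for key in ("SR_min", "SR_max", "singletons_min", "singletons_max"):
            assert s_lo - 1e-9 <= b[key]["sigma"] <= s_hi + 1e-9

    def test_well_mixed_limit_gives_larger_estimates(self, coarse_region, coarse_config):
        """At a matched sample-richness target, the sigma -> inf (Fisher)
        calibration yields more species and singletons than the spatial one."""
        import math

        from scipy.optimize import brentq

        spec = ns.SampleSpec(coarse_config.R)
        for target, contour in [
            (coarse_config.observed_sample_richness, coarse_region.nu_lo),
            (coarse_config.observed_sample_richness
             * coarse_config.richness_correction_factor, coarse_region.nu_hi),
        ]:
            f = lambda lnnu: ns.sample_richness(
                ns.ModelParams(J=coarse_config.J, nu=math.exp(lnnu)),
                spec=spec) - target
            nu_wm = math.exp(brentq(f, math.log(1e-10), math.log(1e-6)))
            p_wm = ns.ModelParams(J=coarse_config.J, nu=nu_wm)
            spatial = [
                ns.spatial_sad(
                    ns.ModelParams(J=coarse_config.J, nu=nu, sigma=s),
                    coarse_config.law)
                for nu, s in zip(contour, coarse_region.sigma_grid)
            ]
            assert ns.fisher_richness(p_wm) > max(s.richness for s in spatial)
            assert ns.fisher_sad(p_wm).singletons > max(s.singletons for s in spatial)

    def test_pipeline_is_deterministic(self, coarse_config):
        r1 = ns.metacommunity_bounds(ns.feasible_region(coarse_config), coarse_config)
        r2 = ns.metacommunity_bounds(ns.feasible_region(coarse_config), coarse_config)
        assert r1 == r2


class TestPredictedSampleSAD:
    def test_mass_and_richness_at_contour_point(self, coarse_region, coarse_config):
        point = coarse_region.corners["A"]
        sad = ns.predicted_sample_sad(point, coarse_config)
        assert sad.total_individuals == pytest.approx(coarse_config.sample_size, rel=1e-3)
        assert sad.richness == pytest.approx(
            coarse_config.observed_sample_richness, rel=1e-3)

    def test_far_off_parameters_diverge_visibly(self, coarse_region, coarse_config):
        """Outside the calibrated region the predicted sample SAD is far off."""
        nu, sigma = coarse_region.corners["A"]
        good = ns.predicted_sample_sad((nu, sigma), coarse_config)
        bad = ns.predicted_sample_sad((nu * 10, sigma), coarse_config)
        assert bad.richness / good.richness > 2.0
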