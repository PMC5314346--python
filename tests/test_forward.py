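"""Forward Moran-process simulator: dynamics, conservation, measurements."""

import numpy as np
import pytest

import neutralscape as ns


class TestInit:
    def test_monodominant(self):
        st = ns.init_community(3, "monodominant", 1)
        assert st.J == 9 and len(np.unique(st.labels)) == 1

    def test_all_distinct(self):
        st = ns.init_community(3, "all-distinct", 1)
        assert len(np.unique(st.labels)) == 9

    def test_same_seed_same_state(self):
        p = ns.ModelParams(J=64, nu=0.1, sigma=1.0)
        outs = []
        for _ in range(2):
            st = ns.init_community(8, "monodominant", 42)
            ns.run(st, p, 5000)
            outs.append(st.labels.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            ns.init_community(1)
        with pytest.raises(ValueError):
            ns.init_community(4, "weird")


class TestDynamics:
    def test_zero_sum_every_site_occupied(self):
        st = ns.init_community(8, "monodominant", 0)
        p = ns.ModelParams(J=64, nu=0.05, sigma=1.0)
        ns.run(st, p, 10_000)
        assert st.labels.size == 64
        assert np.all(st.labels >= 0)
        assert st.species_abundances().sum() == 64

    def test_label_freshness(self):
        """New species always take fresh labels; extinct labels never return."""
        st = ns.init_community(8, "monodominant", 3)
        p = ns.ModelParams(J=64, nu=0.2, sigma=1.0)
        seen_before = {0}
        for _ in range(20):
            old_next = st.next_label
            ns.run(st, p, 500)
            new_labels = set(np.unique(st.labels)) - seen_before
            assert all(lab >= old_next for lab in new_labels)
            seen_before |= set(np.unique(st.labels))
            assert st.labels.max() < st.next_label

    def test_nu_one_every_site_becomes_distinct(self):
        st = ns.init_community(8, "monodominant", 7)
        p = ns.ModelParams(J=64, nu=1.0, sigma=1.0)
        ns.run(st, p, 5000)  # >> J ln J: every site replaced w.h.p.
        assert ns.measure_sad(st).richness == 64

    def test_fixation_without_speciation(self):
        # nu ~ 0: drift fixes a small lattice on a single species
        st = ns.init_community(4, "all-distinct", 9)
        p = ns.ModelParams(J=16, nu=1e-12, sigma=1.0)
        ns.run(st, p, 100_000)
        assert ns.measure_sad(st).richness == 1

    def test_generation_accounting(self):
        st = ns.init_community(8, "monodominant", 0)
        p = ns.ModelParams(J=64, nu=0.1, sigma=1.0)
        ns.run(st, p, 128)
        assert st.generations_elapsed == pytest.approx(2.0)


class TestEquilibration:
    def test_nu_one_plateaus_immediately(self):
        st = ns.init_community(8, "monodominant", 1)
        p = ns.ModelParams(J=64, nu=1.0, sigma=1.0)
        out = ns.run_to_equilibrium(st, p, criterion="plateau", horizon_generations=100)
        assert ns.measure_sad(out).richness == 64

    def test_horizon_grows_as_nu_shrinks(self):
        from neutralscape.forward import default_horizon_generations

        h = [default_horizon_generations(ns.ModelParams(J=1e4, nu=nu, sigma=1.0))
             for nu in (1e-2, 1e-3, 1e-4)]
        assert h[0] < h[1] < h[2]

    def test_richness_reproducible_across_replicates(self, forward_ensemble_64):
        """Replicate-to-replicate richness CV < 15% at stationarity."""
        sr = np.array([len(c) for c in forward_ensemble_64])
        assert sr.std(ddof=1) / sr.mean() < 0.15


class TestMeasurements:
    def test_sad_of_monodominant(self):
        st = ns.init_community(5, "monodominant", 0)
        sad = ns.measure_sad(st)
        assert sad.m.tolist() == [25.0] and sad.n.tolist() == [1.0]

    def test_sad_of_all_distinct(self):
        st = ns.init_community(5, "all-distinct", 0)
        sad = ns.measure_sad(st)
        assert sad.m.tolist() == [1.0] and sad.n.tolist() == [25.0]

    def test_range_of_singleton_is_zero(self):
        st = ns.init_community(6, "monodominant", 0)
        st.labels[2, 3] = 99
        assert ns.measure_range(st, 99) == 0.0

    def test_range_of_uniform_species_is_a_third_of_area(self):
        # 2 * (var_x + var_y) of a uniform occupation = L^2 / 3
        L = 30
        st = ns.init_community(L, "monodominant", 0)
        assert ns.measure_range(st, 0) == pytest.approx(L**2 / 3, rel=0.01)

    def test_range_is_translation_invariant_on_torus(self):
        L = 32
        st = ns.init_community(L, "monodominant", 0)
        st.labels[:] = 0
        st.labels[2:6, 3:8] = 1  # compact block
        r1 = ns.measure_range(st, 1)
        st.labels[:] = 0
        st.labels[(np.arange(2, 6)[:, None] + 29) % L, (np.arange(3, 8)[None, :] + 30) % L] = 1
        r2 = ns.measure_range(st, 1)  # same block wrapped across the seam
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_absent_species_raises(self):
        st = ns.init_community(4, "monodominant", 0)
        with pytest.raises(ValueError):
            ns.measure_range(st, 12345)
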