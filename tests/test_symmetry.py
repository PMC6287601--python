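"""Object-symmetry decomposition and the Procrustes ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micrasym.procrustes import procrustes_distance
from micrasym.simulate import _shape_projectors, default_base_shape
from micrasym.symmetry import (
    SymmetryMap,
    joint_symmetry_gpa,
    reflect_relabel,
    species_asymmetry_means,
    standard_map,
    symmetry_anova,
    symmetry_components,
)
from micrasym.landmark_io import LandmarkDataset, SpecimenRecord

from conftest import make_single_species


class TestSymmetryMap:
    def test_standard_maps_partition_all_landmarks(self):
        for k in (7, 15):
            smap = standard_map(k)
            assert smap.k == k
            used = sorted([i for p in smap.pairs for i in p] + list(smap.axis_points))
            assert used == list(range(1, k + 1))

    def test_subspace_dimensions_sum_to_shape_dimension(self):
        for k in (7, 15):
            d_s, d_a = standard_map(k).subspace_dims()
            assert d_s == d_a
            assert d_s + d_a == 2 * k - 4

    def test_invalid_maps_rejected(self):
        with pytest.raises(ValueError):
            SymmetryMap(pairs=((1, 2), (2, 3)), axis_points=())  # index reused
        with pytest.raises(ValueError):
            SymmetryMap(pairs=((1, 3),), axis_points=(5,))  # not 1..k


class TestReflectRelabel:
    def test_worked_example(self):
        smap = SymmetryMap(pairs=((1, 3),), axis_points=(2,))
        config = np.array([[-1.0, 0.2], [0.0, 1.0], [1.0, 0.0]])
        out = reflect_relabel(config, smap)
        np.testing.assert_allclose(out, [[-1.0, 0.0], [0.0, 1.0], [1.0, 0.2]])

    def test_symmetric_configuration_is_a_fixed_point(self, base7, smap7):
        np.testing.assert_array_equal(reflect_relabel(base7, smap7), base7)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_involution_on_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4)) * 2 + 1
        smap = standard_map(k)
        config = rng.normal(size=(k, 2))
        twice = reflect_relabel(reflect_relabel(config, smap), smap)
        np.testing.assert_array_equal(twice, config)

    def test_map_size_mismatch_raises(self, smap7):
        with pytest.raises(ValueError):
            reflect_relabel(np.zeros((5, 2)), smap7)


class TestJointSymmetryGpa:
    def test_consensus_is_reflection_invariant(self, base7, smap7):
        rng = np.random.default_rng(0)
        configs = base7 + 0.08 * rng.normal(size=(9, 7, 2))
        joint = joint_symmetry_gpa(configs, smap7)
        cons = joint.consensus
        assert np.abs(reflect_relabel(cons, smap7) - cons).max() < 1e-8

    def test_symmetric_inputs_coincide_with_their_mirrors(self, base7, smap7, project7):
        rng = np.random.default_rng(1)
        configs = np.stack(
            [base7 + project7(0.05 * rng.normal(size=14), "sym").reshape(7, 2)
             for _ in range(6)]
        )
        joint = joint_symmetry_gpa(configs, smap7)
        assert np.abs(joint.aligned_originals - joint.aligned_mirrors).max() < 1e-8

    def test_original_to_mirror_distance_is_twice_asymmetric_norm(self, base7, smap7):
        # small variation: the identity is exact only to leading order
        rng = np.random.default_rng(2)
        configs = base7 + 0.005 * rng.normal(size=(5, 7, 2))
        joint = joint_symmetry_gpa(configs, smap7)
        comp = symmetry_components(joint)
        for i in range(5):
            d = procrustes_distance(joint.aligned_originals[i], joint.aligned_mirrors[i])
            assert d == pytest.approx(2 * np.linalg.norm(comp.asymmetric[i]), abs=1e-6)


class TestSymmetryComponents:
    def test_reconstruction_is_exact(self, base7, smap7):
        rng = np.random.default_rng(3)
        configs = base7 + 0.1 * rng.normal(size=(7, 7, 2))
        joint = joint_symmetry_gpa(configs, smap7)
        comp = symmetry_components(joint)
        np.testing.assert_allclose(
            comp.symmetric + comp.asymmetric, joint.aligned_originals, atol=1e-15
        )

    def test_symmetric_input_has_zero_asymmetric_component(self, base7, smap7, project7):
        configs = np.stack([base7, base7 * 1.5 + 2.0])  # same symmetric shape
        joint = joint_symmetry_gpa(configs, smap7)
        comp = symmetry_components(joint)
        assert np.abs(comp.asymmetric).max() < 1e-9

    def test_forward_constructed_asymmetry_is_recovered(self, base7, smap7, project7):
        """base + delta with delta in the asymmetric shape subspace decomposes
        back to delta (up to the small Procrustes nonlinearity)."""
        rng = np.random.default_rng(4)
        delta = project7(0.002 * rng.normal(size=14), "asym")
        configs = np.stack([base7, base7 + delta.reshape(7, 2)])
        joint = joint_symmetry_gpa(configs, smap7)
        comp = symmetry_components(joint)
        recovered = comp.asymmetric[1].reshape(-1)
        assert np.linalg.norm(recovered - delta) < 1e-6


class TestSymmetryAnova:
    def test_pure_positional_asymmetry(self, base7, smap7, project7):
        rng = np.random.default_rng(5)
        delta = project7(0.05 * rng.normal(size=14), "asym")
        ds = make_single_species(base7, project7, n=6, r=2, delta=delta)
        tab = symmetry_anova(ds, smap7, n_perm=99, seed=0)
        assert tab["positional_asymmetry"]["R2"] == pytest.approx(1.0, abs=1e-12)
        assert tab["fluctuating_asymmetry"]["MS"] == pytest.approx(0.0, abs=1e-20)
        assert tab["measurement_error"]["MS"] == pytest.approx(0.0, abs=1e-20)

    def test_pure_symmetric_individual_variation(self, base7, smap7, project7):
        ds = make_single_species(base7, project7, n=6, r=2, sigma_ind=0.05, seed=6)
        tab = symmetry_anova(ds, smap7, n_perm=99, seed=0)
        assert tab["individuals"]["R2"] == pytest.approx(1.0, abs=1e-9)

    def test_sums_of_squares_are_additive(self, base7, smap7, project7):
        ds = make_single_species(
            base7, project7, n=8, r=2, sigma_ind=0.03, sigma_fa=0.01,
            sigma_me=0.005, seed=7,
            delta=project7(0.02 * np.random.default_rng(8).normal(size=14), "asym"),
        )
        tab = symmetry_anova(ds, smap7, n_perm=49, seed=0)
        total_direct = tab.ss_total
        parts = sum(tab[e]["SS"] for e in tab.effects)
        assert parts == pytest.approx(total_direct, rel=1e-12)
        assert sum(tab[e]["R2"] for e in tab.effects) == pytest.approx(1.0, abs=1e-9)

    def test_degrees_of_freedom_follow_object_symmetry_convention(self, base7, smap7, project7):
        n, r = 8, 2
        ds = make_single_species(base7, project7, n=n, r=r, sigma_ind=0.02,
                                 sigma_me=0.01, seed=9)
        tab = symmetry_anova(ds, smap7, n_perm=9, seed=0)
        d = 2 * 3 + 1 - 2  # p pairs = 3, u = 1
        assert tab["individuals"]["df"] == (n - 1) * d
        assert tab["positional_asymmetry"]["df"] == d
        assert tab["fluctuating_asymmetry"]["df"] == (n - 1) * d
        assert tab["measurement_error"]["df"] == n * (r - 1) * 2 * d

    def test_unbalanced_design_rejected_with_counts(self, base7, smap7, project7):
        ds = make_single_species(base7, project7, n=4, r=2, sigma_me=0.01, seed=10)
        records = ds.records[:-1]  # drop one replicate
        with pytest.raises(ValueError, match="replicate counts"):
            symmetry_anova(LandmarkDataset(records), smap7, n_perm=9, seed=0)

    def test_single_replicate_omits_error_row(self, base7, smap7, project7):
        ds = make_single_species(base7, project7, n=6, r=1, sigma_ind=0.02,
                                 sigma_fa=0.01, seed=11)
        tab = symmetry_anova(ds, smap7, n_perm=49, seed=0)
        assert not tab.fa_testable
        assert "measurement_error" not in tab.effects
        assert np.isnan(tab["fluctuating_asymmetry"]["p"])

    def test_same_seed_reproduces_pvalues(self, base7, smap7, project7):
        ds = make_single_species(base7, project7, n=6, r=2, sigma_ind=0.02,
                                 sigma_fa=0.01, sigma_me=0.005, seed=12)
        t1 = symmetry_anova(ds, smap7, n_perm=199, seed=5)
        t2 = symmetry_anova(ds, smap7, n_perm=199, seed=5)
        for eff in t1.effects:
            assert t1[eff]["p"] == t2[eff]["p"] or (
                np.isnan(t1[eff]["p"]) and np.isnan(t2[eff]["p"])
            )

    def test_strong_asymmetry_is_detected(self, base7, smap7, project7):
        """Positional MS far above FA must reject at the permutation floor."""
        rng = np.random.default_rng(13)
        delta = project7(rng.normal(size=14), "asym")
        delta = 0.08 * delta / np.linalg.norm(delta)
        ds = make_single_species(base7, project7, n=30, r=2, delta=delta,
                                 sigma_ind=0.02, sigma_fa=0.01, sigma_me=0.005,
                                 seed=14)
        tab = symmetry_anova(ds, smap7, n_perm=999, seed=1)
        assert tab["positional_asymmetry"]["p"] == pytest.approx(1 / 1000)


class TestSpeciesAsymmetryMeans:
    def test_symmetric_species_mean_equals_its_mirror(self, base7, smap7, project7):
        ds = make_single_species(base7, project7, n=4, r=1, sigma_ind=0.02, seed=15)
        (mean,) = species_asymmetry_means(ds, smap7)
        assert np.abs(mean.mean - mean.mirrored).max() < 1e-8

    def test_opposite_deltas_give_opposite_components(self, base7, smap7, project7):
        rng = np.random.default_rng(16)
        delta = project7(0.04 * rng.normal(size=14), "asym")
        records = []
        for sign, sp in ((1.0, "spA"), (-1.0, "spB")):
            sub = make_single_species(base7, project7, n=5, r=1,
                                      delta=sign * delta, species=sp)
            records.extend(sub.records)
        means = species_asymmetry_means(LandmarkDataset(records), smap7)
        a, b = (m.asym_vector() for m in means)
        assert np.linalg.norm(a) == pytest.approx(np.linalg.norm(b), rel=1e-4)
        assert np.linalg.norm(a + b) < 1e-4

    def test_mirror_component_negates(self, base7, smap7, project7):
        rng = np.random.default_rng(17)
        delta = project7(0.03 * rng.normal(size=14), "asym")
        ds = make_single_species(base7, project7, n=4, r=1, delta=delta, seed=18)
        (mean,) = species_asymmetry_means(ds, smap7)
        mirror_asym = (mean.mirrored - reflect_relabel(mean.mirrored, smap7)) / 2
        np.testing.assert_allclose(mirror_asym, -mean.asymmetry, atol=1e-9)
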