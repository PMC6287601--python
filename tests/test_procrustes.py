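"""Generalized Procrustes superimposition and Procrustes distances."""

import numpy as np
import pytest

from micrasym.procrustes import (
    DegenerateConfigurationError,
    center_scale,
    centroid_size,
    gpa,
    optimal_rotation,
    procrustes_distance,
    rotation_matrix,
    tangent_project,
)


def _grid_min_distance(A, B, step=0.001):
    """Brute-force rotation-grid oracle for the Procrustes distance."""
    A0 = A - A.mean(axis=0)
    A0 = A0 / np.sqrt((A0**2).sum())
    B0 = B - B.mean(axis=0)
    B0 = B0 / np.sqrt((B0**2).sum())
    thetas = np.arange(0.0, 2 * np.pi, step)
    best = np.inf
    for t in thetas:
        R = rotation_matrix(t)
        best = min(best, ((A0 @ R.T - B0) ** 2).sum())
    return np.sqrt(best)


class TestCenterScale:
    def test_definition(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        scaled, size = center_scale(coords)
        assert size == pytest.approx(centroid_size(coords))
        assert np.abs(scaled.mean(axis=0)).max() < 1e-12
        assert (scaled**2).sum() == pytest.approx(1.0)

    def test_idempotent_on_normalized_input(self):
        rng = np.random.default_rng(0)
        scaled, _ = center_scale(rng.normal(size=(5, 2)))
        again, size = center_scale(scaled)
        np.testing.assert_allclose(again, scaled, atol=1e-12)
        assert size == pytest.approx(1.0)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            center_scale(np.ones((3, 2)))


class TestOptimalRotation:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        A, _ = center_scale(rng.normal(size=(6, 2)))
        B = A @ rotation_matrix(np.pi / 2).T
        rotated, angle = optimal_rotation(A, B)
        assert angle == pytest.approx(np.pi / 2)
        np.testing.assert_allclose(rotated, B, atol=1e-12)

    def test_identity_for_equal_inputs(self):
        rng = np.random.default_rng(2)
        A, _ = center_scale(rng.normal(size=(5, 2)))
        _, angle = optimal_rotation(A, A)
        assert angle == pytest.approx(0.0, abs=1e-12)

    def test_mirror_cannot_be_reached_without_reflection(self):
        """A mirrored copy keeps a positive residual under proper rotations,
        and the closed form matches a fine rotation-grid search."""
        rng = np.random.default_rng(3)
        A, _ = center_scale(rng.normal(size=(5, 2)))
        mirror = A * [-1.0, 1.0]
        rotated, angle = optimal_rotation(A, mirror)
        residual = np.sqrt(((rotated - mirror) ** 2).sum())
        assert residual > 0.1
        R = rotation_matrix(angle)
        assert np.linalg.det(R) == pytest.approx(1.0)
        grid = _grid_min_distance(A, mirror, step=0.0001)
        assert residual == pytest.approx(grid, abs=1e-5)

    def test_mismatched_landmark_count_raises(self):
        with pytest.raises(ValueError):
            optimal_rotation(np.zeros((4, 2)), np.zeros((5, 2)))


class TestGpa:
    def test_identical_shapes_collapse_to_zero_distance(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(7, 2))
        B = 3.0 * A @ rotation_matrix(1.2).T + np.array([5.0, -2.0])
        fit = gpa([A, B])
        assert np.abs(fit.aligned[0] - fit.aligned[1]).max() < 1e-9
        np.testing.assert_allclose(fit.aligned[0], fit.consensus, atol=1e-9)

    def test_invariance_to_global_rotation_of_the_dataset(self):
        rng = np.random.default_rng(5)
        configs = rng.normal(size=(8, 6, 2))
        rotated = configs @ rotation_matrix(0.8).T
        d1 = [procrustes_distance(a, b) for a in configs for b in configs]
        d2 = [procrustes_distance(a, b) for a in rotated for b in rotated]
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_aligned_configurations_are_normalized(self):
        rng = np.random.default_rng(6)
        fit = gpa(rng.normal(size=(10, 7, 2)))
        centroids = fit.aligned.mean(axis=1)
        sizes = np.sqrt((fit.aligned**2).sum(axis=(1, 2)))
        assert np.abs(centroids).max() < 1e-9
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)

    def test_consensus_is_a_fixed_point(self):
        """One extra alignment pass moves the consensus by less than 1e-6."""
        rng = np.random.default_rng(7)
        fit = gpa(rng.normal(size=(10, 7, 2)), tol=1e-14)
        realigned = np.stack(
            [optimal_rotation(cfg, fit.consensus)[0] for cfg in fit.aligned]
        )
        assert np.abs(realigned.mean(axis=0) - fit.consensus).max() < 1e-6

    def test_consensus_equals_mean_of_aligned(self):
        rng = np.random.default_rng(8)
        fit = gpa(rng.normal(size=(6, 5, 2)))
        np.testing.assert_allclose(fit.consensus, fit.aligned.mean(axis=0), atol=1e-12)


class TestProcrustesDistance:
    def test_zero_for_identical_and_similarity_transformed(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(6, 2))
        assert procrustes_distance(A, A) == pytest.approx(0.0, abs=1e-12)
        B = 0.3 * A @ rotation_matrix(-2.2).T + np.array([1.0, 9.0])
        assert procrustes_distance(A, B) == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            A = rng.normal(size=(4, 2))
            B = rng.normal(size=(4, 2))
            assert procrustes_distance(A, B) == pytest.approx(
                _grid_min_distance(A, B), abs=1e-5
            )

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A, B, C = rng.normal(size=(3, 5, 2))
            dab = procrustes_distance(A, B)
            dba = procrustes_distance(B, A)
            assert dab == pytest.approx(dba, abs=1e-10)
            assert dab <= procrustes_distance(A, C) + procrustes_distance(C, B) + 1e-10


class TestTangentProjection:
    def test_consensus_maps_to_zero_and_columns_are_centered(self):
        rng = np.random.default_rng(12)
        fit = gpa(rng.normal(size=(12, 7, 2)))
        T = tangent_project(fit)
        assert np.abs(T.mean(axis=0)).max() < 1e-8
        m = fit.consensus.reshape(-1)
        m = m / np.linalg.norm(m)
        assert np.abs(T @ m).max() < 1e-10

    def test_tangent_distances_approximate_procrustes_distances(self):
        """For low-variance samples the two metrics agree to < 1e-3 relative."""
        rng = np.random.default_rng(13)
        base = rng.normal(size=(7, 2))
        configs = base + 0.005 * rng.normal(size=(8, 7, 2))
        fit = gpa(configs)
        T = tangent_project(fit)
        for i in range(4):
            for j in range(i + 1, 8):
                dp = procrustes_distance(configs[i], configs[j])
                dt = np.linalg.norm(T[i] - T[j])
                assert dt == pytest.approx(dp, rel=1e-3)
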