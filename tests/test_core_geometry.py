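"""Procrustes machinery: centering, size, rotation, GPA, shape PCA."""

import numpy as np
import pytest

from lamorph.core_geometry import (
    LandmarkConfiguration,
    center,
    centroid_size,
    gpa,
    optimal_rotation,
    shape_pca,
)
from lamorph.errors import (
    DegenerateConfigurationError,
    InsufficientDataError,
    InvalidInputError,
    ShapeMismatchError,
)

from conftest import random_config, random_rotation

SQUARE = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0]], dtype=float)


class TestCenter:
    def test_square_centroid_subtracted(self):
        c = center(SQUARE)
        assert np.allclose(c, SQUARE - np.array([1.0, 1.0, 0.0]))
        assert np.allclose(c[:, 2], 0)

    def test_already_centered_unchanged(self, rng):
        x = random_config(rng)
        x -= x.mean(axis=0)
        assert np.allclose(center(x), x)

    def test_large_cloud_zero_column_means(self, rng):
        x = random_config(rng, k=1297, scale=25.0)
        assert np.all(np.abs(center(x).mean(axis=0)) < 1e-12)

    def test_configuration_type_preserved(self, rng):
        cfg = LandmarkConfiguration(random_config(rng))
        out = center(cfg)
        assert isinstance(out, LandmarkConfiguration)
        assert np.allclose(out.centroid(), 0)

    def test_non_finite_rejected(self):
        with pytest.raises(InvalidInputError):
            LandmarkConfiguration(np.array([[np.nan, 0, 0], [1, 1, 1]]))


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]], float)
        assert centroid_size(sq) == pytest.approx(np.sqrt(8))

    def test_homogeneous_scaling(self, rng):
        x = random_config(rng)
        assert centroid_size(3.5 * x) == pytest.approx(3.5 * centroid_size(x))

    def test_rotation_invariance(self, rng):
        x = random_config(rng)
        r = random_rotation(rng)
        assert abs(centroid_size(x @ r) - centroid_size(x)) < 1e-10

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((5, 3)))


class TestOptimalRotation:
    def test_identity_for_equal_configs(self, rng):
        x = center(random_config(rng))
        assert np.allclose(optimal_rotation(x, x), np.eye(3), atol=1e-10)

    def test_exact_recovery_of_known_rotation(self, rng):
        x = center(random_config(rng))
        r = random_rotation(rng)
        rot = optimal_rotation(x @ r, x)
        assert np.allclose(rot, r.T, atol=1e-10)
        assert np.linalg.norm((x @ r) @ rot - x) < 1e-10

    def test_proper_rotation_under_reflection_pull(self, rng):
        # target is a mirrored copy; the optimum must still have det +1
        x = center(random_config(rng))
        y = x * np.array([1, 1, -1])
        r = optimal_rotation(x, y)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_beats_random_search(self, rng):
        x = center(random_config(rng))
        y = center(x @ random_rotation(rng) + 0.3 * rng.standard_normal(x.shape))
        best = np.linalg.norm(x @ optimal_rotation(x, y) - y)
        for _ in range(1000):
            assert np.linalg.norm(x @ random_rotation(rng) - y) >= best - 1e-12

    def test_mismatched_k_rejected(self, rng):
        with pytest.raises(ShapeMismatchError):
            optimal_rotation(random_config(rng, k=10), random_config(rng, k=12))


class TestGPA:
    def test_rigid_copies_align_exactly(self, rng):
        x = center(random_config(rng))
        configs = [x @ random_rotation(rng) + rng.uniform(-5, 5, 3) for _ in range(6)]
        res = gpa(configs, space="SSS")
        assert np.all(np.abs(res.aligned - res.aligned[0]) < 1e-8)
        assert np.allclose(res.grand_mean, res.aligned[0], atol=1e-8)

    def test_two_config_mean_is_midpoint(self, rng):
        a = center(random_config(rng))
        b = center(a + 0.2 * rng.standard_normal(a.shape))
        res = gpa([a, b], space="SSS")
        assert np.allclose(res.grand_mean, res.aligned.mean(axis=0))
        d_mid = np.linalg.norm(res.aligned[0] - res.grand_mean)
        assert d_mid == pytest.approx(np.linalg.norm(res.aligned[1] - res.grand_mean))

    def test_objective_monotone_non_increasing(self, rng):
        configs = [random_config(rng) for _ in range(8)]
        res = gpa(configs, space="SSS")
        hist = np.asarray(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_sss_preserves_centroid_sizes(self, rng):
        configs = [random_config(rng, scale=s) for s in (5, 10, 20, 40)]
        res = gpa(configs, space="SSS")
        for orig, aligned in zip(configs, res.aligned):
            rel = abs(centroid_size(aligned) - centroid_size(orig)) / centroid_size(orig)
            assert rel < 1e-9
        assert np.all(res.scales == 1)

    def test_ss_scales_to_unit_size(self, rng):
        configs = [random_config(rng, scale=s) for s in (5, 10, 20)]
        res = gpa(configs, space="SS")
        for aligned in res.aligned:
            assert centroid_size(aligned) == pytest.approx(1.0, abs=1e-9)

    def test_common_rigid_motion_invariance(self, rng):
        configs = [random_config(rng) for _ in range(5)]
        r = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        moved = [c @ r + t for c in configs]
        d0 = _pairwise(gpa(configs, space="SSS").aligned)
        d1 = _pairwise(gpa(moved, space="SSS").aligned)
        assert np.allclose(d0, d1, atol=1e-8)

    def test_rotations_are_proper(self, rng):
        res = gpa([random_config(rng) for _ in range(4)], space="SSS")
        for r in res.rotations:
            assert np.linalg.det(r) == pytest.approx(1.0)

    def test_non_convergence_flagged_not_silent(self, rng):
        configs = [random_config(rng) for _ in range(6)]
        with pytest.warns(RuntimeWarning):
            res = gpa(configs, space="SSS", tol=0.0, max_iter=2)
        assert not res.converged

    def test_single_config_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            gpa([random_config(rng)])


def _pairwise(aligned):
    n = aligned.shape[0]
    return np.array(
        [np.linalg.norm(aligned[i] - aligned[j])
         for i in range(n) for j in range(i + 1, n)]
    )


class TestShapePCA:
    def test_planar_data_two_nonzero_eigenvalues(self, rng):
        base = center(random_config(rng, k=12))
        d1 = rng.standard_normal(base.shape)
        d2 = rng.standard_normal(base.shape)
        data = np.stack(
            [base + a * d1 + b * a * d2 for a, b in rng.uniform(-1, 1, (20, 2))]
        )
        p = shape_pca(data)
        assert np.sum(p.eigenvalues > 1e-10 * p.eigenvalues[0]) == 2

    def test_variance_fractions_and_cumulative(self, rng):
        data = np.stack([random_config(rng, k=10) for _ in range(15)])
        p = shape_pca(data)
        assert p.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(p.cumulative_fraction) >= -1e-12)
        assert p.variance_fraction[:3].sum() == pytest.approx(p.cumulative_fraction[2])

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        data = np.stack([random_config(rng, k=10) for _ in range(15)])
        p = shape_pca(data)
        flat = data.reshape(15, -1)
        total = ((flat - flat.mean(0)) ** 2).sum() / (15 - 1)
        assert p.eigenvalues.sum() == pytest.approx(total)

    def test_full_reconstruction_lossless(self, rng):
        data = np.stack([random_config(rng, k=8) for _ in range(10)])
        p = shape_pca(data)
        rec = p.reconstruct(p.scores)
        assert np.allclose(rec, data.reshape(10, -1), atol=1e-8)

    def test_scores_zero_mean_and_loadings_orthonormal(self, rng):
        data = np.stack([random_config(rng, k=8) for _ in range(10)])
        p = shape_pca(data)
        assert np.all(np.abs(p.scores.mean(axis=0)) < 1e-9)
        assert np.allclose(p.loadings.T @ p.loadings, np.eye(p.n_components),
                           atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        data = np.stack([random_config(rng, k=8) for _ in range(10)])
        p = shape_pca(data)
        for j in range(p.n_components):
            idx = np.argmax(np.abs(p.loadings[:, j]))
            assert p.loadings[idx, j] > 0

    def test_external_centering(self, rng):
        data = np.stack([random_config(rng, k=8) for _ in range(10)])
        ext = data.reshape(10, -1).mean(axis=0) + 0.5
        p = shape_pca(data, center_on=ext)
        assert np.allclose(p.mean_vector, ext)
        assert np.allclose(p.reconstruct(p.scores), data.reshape(10, -1), atol=1e-8)

    def test_insufficient_observations_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            shape_pca(np.stack([random_config(rng)]))
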