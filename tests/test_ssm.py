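"""Procrustes alignment and the PCA shape model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lvshape.mesh import TopologyError
from lvshape.ssm import (
    align_meshes,
    fit_pca,
    project,
    reconstruct,
    select_modes,
    synthesize_extreme,
)


@pytest.fixture(scope="module")
def aligned_sample(random_shape_sample):
    return align_meshes(random_shape_sample)


@pytest.fixture(scope="module")
def pca_model(aligned_sample):
    return fit_pca(aligned_sample)


class TestAlignment:
    def test_translated_copies_collapse(self, uniform_wall_mesh):
        m1 = uniform_wall_mesh
        m2 = m1.with_points(m1.as_points() + [5.0, -3.0, 11.0])
        v1, v2 = align_meshes([m1, m2])
        assert np.abs(v1 - v2).max() < 1e-9

    def test_rotated_copy_aligned_back(self, uniform_wall_mesh):
        rot = Rotation.from_euler("zyx", [25.0, 10.0, -15.0], degrees=True)
        rotated = uniform_wall_mesh.with_points(rot.apply(uniform_wall_mesh.as_points()))
        v1, v2 = align_meshes([uniform_wall_mesh, rotated])
        assert np.abs(v1 - v2).max() < 1e-6

    def test_scaling_is_preserved_as_shape_signal(self, uniform_wall_mesh):
        scaled = uniform_wall_mesh.with_points(uniform_wall_mesh.as_points() * 1.2)
        v1, v2 = align_meshes([uniform_wall_mesh, scaled])
        centred1 = v1.reshape(-1, 3) - v1.reshape(-1, 3).mean(axis=0)
        centred2 = v2.reshape(-1, 3) - v2.reshape(-1, 3).mean(axis=0)
        ratio = np.linalg.norm(centred2) / np.linalg.norm(centred1)
        assert ratio == pytest.approx(1.2, rel=1e-6)

    def test_topology_mismatch_rejected(self, uniform_wall_mesh):
        from lvshape.synthetic import LVGeometryParams, generate_lv_surface

        other = generate_lv_surface(LVGeometryParams(), n_circ=32, n_long=16)
        with pytest.raises(TopologyError):
            align_meshes([uniform_wall_mesh, other])


class TestPCA:
    def test_two_shapes_give_midpoint_mean_and_one_mode(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        b = a + rng.normal(size=30)
        with pytest.raises(ValueError):
            fit_pca([a, b])
        model = fit_pca([a, b, a, b])
        np.testing.assert_allclose(model.mean_shape, (a + b) / 2.0, atol=1e-12)
        assert model.variances[0] > 1e-12
        assert np.all(model.variances[1:] < 1e-20)

    def test_variance_conservation(self, aligned_sample, pca_model):
        X = np.asarray(aligned_sample)
        total = X.var(axis=0, ddof=1).sum()
        assert pca_model.variances.sum() == pytest.approx(total, rel=1e-8)

    def test_matches_dense_covariance_eigendecomposition(self):
        """Brute-force oracle on a low-dimensional random sample."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 40)) @ rng.normal(size=(40, 40))
        model = fit_pca(list(X))
        C = np.cov(X.T, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:19]
        np.testing.assert_allclose(model.variances, evals[order], rtol=1e-8)
        for k in range(19):
            v = evecs[:, order[k]]
            cos = abs(np.dot(v, model.modes[:, k]))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_modes_and_sorted_variances(self, pca_model):
        gram = pca_model.modes.T @ pca_model.modes
        np.testing.assert_allclose(gram, np.eye(pca_model.n_modes), atol=1e-8)
        assert np.all(np.diff(pca_model.variances) <= 1e-12)

    def test_repeated_fit_is_bit_identical(self, aligned_sample):
        m1 = fit_pca(aligned_sample)
        m2 = fit_pca(aligned_sample)
        assert np.array_equal(m1.modes, m2.modes)
        assert np.array_equal(m1.variances, m2.variances)


class TestModeSelection:
    @pytest.mark.parametrize(
        "ratios, threshold, expected",
        [
            ([0.5, 0.3, 0.15, 0.05], 0.90, 3),
            ([0.95, 0.05], 0.90, 1),
            ([0.6, 0.3, 0.1], 0.90, 2),  # hitting the threshold exactly counts
        ],
    )
    def test_cumulative_variance_rule(self, ratios, threshold, expected):
        from lvshape.ssm import PCAModel

        ratios = np.asarray(ratios)
        model = PCAModel(
            mean_shape=np.zeros(4),
            modes=np.eye(4)[:, : len(ratios)],
            variances=ratios.copy(),
            explained_ratio=ratios,
            n_subjects=10,
        )
        assert select_modes(model, threshold) == expected


class TestProjection:
    def test_mean_shape_has_zero_coefficients(self, pca_model):
        coeffs = project(pca_model, pca_model.mean_shape)
        assert np.abs(coeffs.raw).max() < 1e-9

    def test_three_sd_step_standardizes_to_three(self, pca_model):
        x = pca_model.mean_shape + 3.0 * pca_model.sd()[0] * pca_model.modes[:, 0]
        std = project(pca_model, x).standardized[0]
        assert std[0] == pytest.approx(3.0, abs=1e-8)
        assert np.abs(std[1:]).max() < 1e-8

    def test_training_scores_centred_and_unit_sd(self, aligned_sample, pca_model):
        coeffs = project(pca_model, np.asarray(aligned_sample))
        assert np.abs(coeffs.raw.mean(axis=0)).max() < 1e-8
        sds = coeffs.standardized.std(axis=0, ddof=1)
        np.testing.assert_allclose(sds[pca_model.variances > 1e-12], 1.0, atol=1e-6)

    def test_full_rank_round_trip(self, aligned_sample, pca_model):
        X = np.asarray(aligned_sample)
        rec = reconstruct(pca_model, project(pca_model, X).raw)
        scale = np.abs(X).max()
        assert np.abs(rec - X).max() / scale < 1e-8

    def test_truncation_error_equals_discarded_variance(self, aligned_sample, pca_model):
        X = np.asarray(aligned_sample)
        raw = project(pca_model, X).raw
        k = 4
        rec = reconstruct(pca_model, raw[:, :k])
        err = np.sum((rec - X) ** 2)
        expected = (len(X) - 1) * pca_model.variances[k:].sum()
        assert err == pytest.approx(expected, rel=1e-6)

    def test_dimension_mismatch_rejected(self, pca_model):
        with pytest.raises(ValueError):
            project(pca_model, np.zeros(10))


class TestSynthesis:
    def test_zero_step_returns_mean(self, pca_model, uniform_wall_mesh):
        direction = np.zeros(pca_model.n_modes)
        direction[0] = 1.0
        vec = synthesize_extreme(pca_model, direction, 0.0)
        np.testing.assert_allclose(vec, pca_model.mean_shape, atol=1e-12)

    def test_extremes_symmetric_about_mean(self, pca_model):
        direction = np.zeros(pca_model.n_modes)
        direction[1] = 1.0
        plus = synthesize_extreme(pca_model, direction, 3.0)
        minus = synthesize_extreme(pca_model, direction, -3.0)
        np.testing.assert_allclose((plus + minus) / 2, pca_model.mean_shape, atol=1e-9)

    def test_first_mode_direction_matches_reconstruct(self, pca_model):
        direction = np.zeros(pca_model.n_modes)
        direction[0] = 1.0
        vec = synthesize_extreme(pca_model, direction, 3.0)
        raw = np.zeros(pca_model.n_modes)
        raw[0] = 3.0 * pca_model.sd()[0]
        np.testing.assert_allclose(vec, reconstruct(pca_model, raw), atol=1e-9)

    def test_zero_direction_rejected(self, pca_model):
        with pytest.raises(ValueError):
            synthesize_extreme(pca_model, np.zeros(3), 3.0)

    def test_latent_factors_captured_by_leading_modes(self):
        """q independent generative factors concentrate >=95% of variance in
        the first q modes when noise is small."""
        rng = np.random.default_rng(9)
        q, dim, n = 3, 60, 80
        basis = np.linalg.qr(rng.normal(size=(dim, q)))[0]
        scores = rng.normal(size=(n, q)) * np.array([3.0, 2.0, 1.0])
        X = scores @ basis.T + 0.05 * rng.normal(size=(n, dim))
        model = fit_pca(list(X))
        assert model.explained_ratio[:q].sum() > 0.95
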