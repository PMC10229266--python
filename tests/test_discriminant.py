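"""Fisher LDA axes, Z-scores, AUC and cross-validation."""

import warnings

import numpy as np
import pytest

from lvshape.discriminant import (
    DegenerateSeparationError,
    auc,
    axis_extreme_shapes,
    fit_lda,
    loo_cv_auc,
    zscore,
)


def exact_covariance_groups(target_cov, delta, n=200, dim=None, seed=0):
    """Two groups whose pooled within-class sample covariance equals
    ``target_cov`` exactly (group B = group A + delta)."""
    dim = len(delta) if dim is None else dim
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, dim))
    A -= A.mean(axis=0)
    cov = A.T @ A / (n - 1)
    whiten = np.linalg.inv(np.linalg.cholesky(cov))
    A = A @ whiten.T @ np.linalg.cholesky(target_cov).T
    return A, A + np.asarray(delta)


class TestFitLDA:
    def test_identity_covariance_recovers_mean_difference(self):
        A, B = exact_covariance_groups(np.eye(3), [1.0, 0.0, 0.0])
        model = fit_lda(A, B, shrinkage=0.0)
        w = model.weights / np.linalg.norm(model.weights)
        np.testing.assert_allclose(np.abs(w), [1.0, 0.0, 0.0], atol=1e-9)

    def test_anisotropic_toy_solution(self):
        """S_w = diag(2, 1), delta = (1, 1): direction proportional to (0.5, 1)."""
        A, B = exact_covariance_groups(np.diag([2.0, 1.0]), [1.0, 1.0])
        model = fit_lda(A, B, shrinkage=0.0)
        w = model.weights / model.weights[1]
        np.testing.assert_allclose(w, [0.5, 1.0], atol=1e-9)

    def test_identical_groups_degenerate(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(10, 3))
        with pytest.raises(DegenerateSeparationError):
            fit_lda(A, A.copy())

    def test_orientation_gives_positive_group_higher_z(self):
        A, B = exact_covariance_groups(np.eye(2), [-1.0, 0.5])
        model = fit_lda(A, B)
        z_a, z_b = zscore(model, A), zscore(model, B)
        assert z_b.mean() > z_a.mean()

    def test_training_z_normalized(self):
        A, B = exact_covariance_groups(np.eye(4), [0.8, 0.0, 0.3, 0.0])
        model = fit_lda(A, B)
        z = zscore(model, np.vstack([A, B]))
        assert z.mean() == pytest.approx(0.0, abs=1e-8)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_scale_invariance_of_z_scores(self):
        A, B = exact_covariance_groups(np.diag([2.0, 1.0]), [1.0, 0.5])
        m1 = fit_lda(A, B)
        m2 = fit_lda(10.0 * A, 10.0 * B)
        np.testing.assert_allclose(
            zscore(m1, np.vstack([A, B])),
            zscore(m2, 10.0 * np.vstack([A, B])),
            atol=1e-8,
        )

    def test_fisher_criterion_near_analytic_optimum(self):
        """Fitted axis reaches >=99.9% of the empirical Fisher optimum."""

        def criterion(w, s_w, delta):
            return (w @ delta) ** 2 / (w @ s_w @ w)

        rng = np.random.default_rng(7)
        for _ in range(10):
            dim = 4
            M = rng.normal(size=(dim, dim))
            cov = M @ M.T + 0.5 * np.eye(dim)
            delta = rng.normal(size=dim)
            L = np.linalg.cholesky(cov)
            A = rng.normal(size=(1000, dim)) @ L.T
            B = rng.normal(size=(1000, dim)) @ L.T + delta
            model = fit_lda(A, B)  # default Ledoit-Wolf shrinkage
            centred = np.vstack([A - A.mean(0), B - B.mean(0)])
            s_emp = centred.T @ centred / (len(centred) - 2)
            d_emp = B.mean(0) - A.mean(0)
            best = criterion(np.linalg.solve(s_emp, d_emp), s_emp, d_emp)
            fitted = criterion(model.weights, s_emp, d_emp)
            assert fitted >= 0.999 * best

    def test_mode_subset_restriction(self):
        A, B = exact_covariance_groups(np.eye(5), [1.0, 0.0, 0.0, 0.0, 2.0])
        model = fit_lda(A, B, included_modes=np.array([0, 1]))
        assert model.weights.shape == (2,)
        z = zscore(model, np.vstack([A, B]))
        assert np.isfinite(z).all()


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0]) == 0.5

    def test_three_of_four_pairs_ordered(self):
        assert auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestLOO:
    def test_separated_groups_reach_auc_one(self):
        A = np.column_stack([np.full(5, -3.0), np.zeros(5)]) + 0.01 * np.arange(5)[:, None]
        B = np.column_stack([np.full(5, 3.0), np.zeros(5)]) + 0.01 * np.arange(5)[:, None]
        X = np.vstack([A, B])
        y = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        report = loo_cv_auc(X, y, shrinkage=0.1)
        assert report.auc_loo == 1.0
        assert report.auc_resubstitution == 1.0

    def test_fold_equivalence_with_inline_oracle(self):
        """n=6: every fold must equal an independently coded refit."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        X[3:] += [1.5, 0.5]
        y = np.r_[np.zeros(3, bool), np.ones(3, bool)]
        report = loo_cv_auc(X, y, shrinkage=0.2)

        held = []
        for i in range(6):
            keep = np.delete(np.arange(6), i)
            Xk, yk = X[keep], y[keep]
            model = fit_lda(Xk[~yk], Xk[yk], shrinkage=0.2)
            held.append(float(zscore(model, X[i : i + 1])[0]))
        assert report.auc_loo == pytest.approx(auc(held, y), abs=1e-12)

    def test_null_labels_give_chance_level(self):
        """Permuted labels: mean LOO AUC within 0.5 +- 0.03 over 100 reps."""
        rng = np.random.default_rng(17)
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(100):
                X = rng.normal(size=(200, 5))
                y = np.zeros(200, bool)
                y[rng.permutation(200)[:100]] = True
                aucs.append(loo_cv_auc(X, y).auc_loo)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_small_or_single_class_inputs_rejected(self):
        with pytest.raises(ValueError):
            loo_cv_auc(np.zeros((3, 2)), [0, 1, 1])


@pytest.fixture(scope="module")
def trained_setup(random_shape_sample):
    from lvshape.ssm import align_meshes, fit_pca, project, select_modes

    vectors = align_meshes(random_shape_sample)
    pca = fit_pca(vectors)
    k = select_modes(pca, 0.90)
    std = project(pca, np.asarray(vectors)).standardized
    # split by the first mode sign to get two separable halves
    labels = std[:, 0] > np.median(std[:, 0])
    model = fit_lda(
        std[~labels][:, :k], std[labels][:, :k],
        included_modes=np.arange(k),
    )
    model.included_modes = np.arange(k)
    return pca, model, std, labels


class TestAxisExtremes:

    def test_plus_extreme_reprojects_to_plus_three(self, trained_setup, random_shape_sample):
        pca, model, std, _ = trained_setup
        from lvshape.ssm import project

        minus, plus = axis_extreme_shapes(model, pca, 3.0)
        z_plus = zscore(model, project(pca, plus).standardized)[0]
        z_minus = zscore(model, project(pca, minus).standardized)[0]
        # extremes are symmetric about the mean shape, whose Z is -mean/sd
        z_mean = -model.score_mean / model.score_sd
        assert z_plus - z_mean == pytest.approx(3.0, abs=1e-6)
        assert z_minus - z_mean == pytest.approx(-3.0, abs=1e-6)

    def test_midpoint_is_mean_shape(self, trained_setup):
        pca, model, _, _ = trained_setup
        minus, plus = axis_extreme_shapes(model, pca, 3.0)
        np.testing.assert_allclose((minus + plus) / 2.0, pca.mean_shape, atol=1e-9)

    def test_zero_weights_rejected(self, trained_setup):
        import dataclasses

        pca, model, _, _ = trained_setup
        broken = dataclasses.replace(model, weights=np.zeros_like(model.weights))
        with pytest.raises(ValueError):
            axis_extreme_shapes(broken, pca, 3.0)
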