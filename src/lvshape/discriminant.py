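"""Fisher LDA remodelling axes, Z-scores and AUC validation.

Each remodelling axis is the Fisher linear discriminant between two cohort
strata in standardized PCA-coefficient space, restricted to the modes that
reach the cumulative explained-variance rule.  A subject's position along an
axis is reported as a Z-score: the discriminant score normalized by the
pooled training mean and SD and oriented so that positive Z points at the
"obstructive-like" (or genotype-positive) group.

The within-class covariance is regularized with Ledoit–Wolf shrinkage by
default — with a couple of dozen modes and potentially small strata the
pooled scatter can be ill-conditioned, and shrinkage keeps the axis stable
without a tuning parameter.  Discriminative performance is summarized by the
area under the ROC curve (Mann–Whitney formulation, ties counted half) in
resubstitution and leave-one-out cross-validation; only the continuous Z is
ever used, never a hard classification threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.covariance import LedoitWolf

from .mesh import LVMesh
from .ssm import PCAModel, ShapeCoefficients, synthesize_extreme

__all__ = [
    "LDAModel",
    "ValidationReport",
    "DegenerateSeparationError",
    "fit_lda",
    "zscore",
    "auc",
    "loo_cv_auc",
    "axis_extreme_shapes",
]


class DegenerateSeparationError(ValueError):
    """Raised when the two groups have identical coefficient means."""


@dataclass
class LDAModel:
    """Trained Fisher discriminant axis in standardized-coefficient space.

    ``weights`` acts on the columns listed in ``included_modes``; training
    Z-scores have mean 0 and SD 1 by construction, and the orientation flag
    records whether the raw Fisher direction was flipped so that the positive
    class (second group passed to :func:`fit_lda`) has the larger mean Z.
    """

    weights: np.ndarray
    included_modes: np.ndarray
    score_mean: float
    score_sd: float
    orientation_sign: float
    labels: tuple[str, str]
    shrinkage: str | float = "ledoit-wolf"

    def direction_standardized(self, n_modes: int | None = None) -> np.ndarray:
        """Unit direction of the axis, zero-padded to ``n_modes`` columns."""
        k = int(self.included_modes.max()) + 1 if n_modes is None else n_modes
        d = np.zeros(k)
        d[self.included_modes] = self.weights
        return d / np.linalg.norm(d)


@dataclass
class ValidationReport:
    """AUC of an axis in resubstitution and leave-one-out scenarios."""

    auc_resubstitution: float
    auc_loo: float
    n_per_group: tuple[int, int]
    threshold_mmHg: float | None = None
    n_folds_skipped: int = 0


def _as_matrix(coeffs) -> np.ndarray:
    if isinstance(coeffs, ShapeCoefficients):
        return coeffs.standardized
    return np.atleast_2d(np.asarray(coeffs, dtype=float))


def fit_lda(
    coeffs_a,
    coeffs_b,
    included_modes: np.ndarray | None = None,
    labels: tuple[str, str] = ("A", "B"),
    shrinkage: str | float = "ledoit-wolf",
) -> LDAModel:
    """Fisher discriminant between two groups of standardized coefficients.

    ``coeffs_a``/``coeffs_b`` are (n_i, K) matrices (or
    :class:`~lvshape.ssm.ShapeCoefficients`); columns outside
    ``included_modes`` are ignored.  The weight vector solves
    ``S_w w = mu_b - mu_a`` with the pooled within-class covariance ``S_w``
    estimated under the requested shrinkage ("ledoit-wolf", or a fixed
    intensity in [0, 1]; 0 = plain pooled covariance with a fallback ridge if
    numerically singular).  The positive class is group B (``labels[1]``).
    """
    A = _as_matrix(coeffs_a)
    B = _as_matrix(coeffs_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("coefficient matrices differ in mode count")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if included_modes is None:
        included_modes = np.arange(A.shape[1])
    included_modes = np.asarray(included_modes, dtype=int)
    A = A[:, included_modes]
    B = B[:, included_modes]

    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    delta = mu_b - mu_a
    if np.linalg.norm(delta) < 1e-12:
        raise DegenerateSeparationError("group means are identical")

    centred = np.vstack([A - mu_a, B - mu_b])
    s_w = _within_covariance(centred, len(A) + len(B), shrinkage)
    weights = _solve_spd(s_w, delta)

    scores = np.concatenate([A @ weights, B @ weights])
    mean_a = float(np.mean(scores[: len(A)]))
    mean_b = float(np.mean(scores[len(A) :]))
    orientation = 1.0
    if mean_b < mean_a:
        orientation = -1.0
        weights = -weights
        scores = -scores
    score_mean = float(scores.mean())
    score_sd = float(scores.std(ddof=1))
    if score_sd < 1e-15:
        raise DegenerateSeparationError("training scores are constant")
    return LDAModel(
        weights=weights,
        included_modes=included_modes,
        score_mean=score_mean,
        score_sd=score_sd,
        orientation_sign=orientation,
        labels=labels,
        shrinkage=shrinkage,
    )


def _within_covariance(centred: np.ndarray, n: int, shrinkage) -> np.ndarray:
    p = centred.shape[1]
    if shrinkage == "ledoit-wolf":
        lw = LedoitWolf(assume_centered=True).fit(centred)
        return lw.covariance_
    gamma = float(shrinkage)
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("fixed shrinkage intensity must lie in [0, 1]")
    emp = centred.T @ centred / max(n - 2, 1)
    if gamma == 0.0:
        return emp
    mu = np.trace(emp) / p
    return (1.0 - gamma) * emp + gamma * mu * np.eye(p)


def _solve_spd(s_w: np.ndarray, delta: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(s_w)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn(
            "singular within-class covariance; applying ridge regularization",
            stacklevel=3,
        )
        s_w = s_w + 1e-8 * np.trace(s_w) / len(s_w) * np.eye(len(s_w))
    return np.linalg.solve(s_w, delta)


def zscore(model: LDAModel, coeffs) -> np.ndarray:
    """Z-scores of subjects along a trained axis (applicable out of sample)."""
    X = _as_matrix(coeffs)
    if X.shape[1] < int(model.included_modes.max()) + 1:
        raise ValueError("coefficient matrix has too few modes for this axis")
    scores = X[:, model.included_modes] @ model.weights
    return (scores - model.score_mean) / model.score_sd


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann–Whitney formulation.

    Fraction of (positive, negative) pairs where the positive scores higher,
    ties counted one half.  ``labels`` are truthy for the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def loo_cv_auc(
    coeffs,
    labels,
    included_modes: np.ndarray | None = None,
    shrinkage: str | float = "ledoit-wolf",
    threshold_mmHg: float | None = None,
) -> ValidationReport:
    """Resubstitution and leave-one-out AUC of a Fisher axis.

    For every subject the discriminant (weights and Z normalization) is refit
    on the remaining n-1 subjects and the held-out subject is scored by the
    fold's model; the LOO AUC is computed over those held-out Z-scores.  The
    PCA basis is frozen throughout — only the discriminant is refit per fold.
    Folds that would empty a class are skipped with a warning.
    """
    X = _as_matrix(coeffs)
    y = np.asarray(labels, dtype=bool)
    if len(X) != len(y):
        raise ValueError("coefficients and labels differ in length")
    if len(X) < 4 or y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need n >= 4 with at least 2 subjects per class")

    full = fit_lda(
        X[~y], X[y], included_modes=included_modes, shrinkage=shrinkage
    )
    resub = auc(zscore(full, X), y)

    held_scores, held_labels = [], []
    skipped = 0
    for i in range(len(X)):
        keep = np.ones(len(X), dtype=bool)
        keep[i] = False
        yk = y[keep]
        if yk.sum() < 2 or (~yk).sum() < 2:
            skipped += 1
            warnings.warn(f"LOO fold {i} skipped: class emptied", stacklevel=2)
            continue
        Xk = X[keep]
        fold = fit_lda(
            Xk[~yk], Xk[yk], included_modes=included_modes, shrinkage=shrinkage
        )
        held_scores.append(float(zscore(fold, X[i : i + 1])[0]))
        held_labels.append(bool(y[i]))
    loo = auc(held_scores, held_labels)
    return ValidationReport(
        auc_resubstitution=resub,
        auc_loo=loo,
        n_per_group=(int((~y).sum()), int(y.sum())),
        threshold_mmHg=threshold_mmHg,
        n_folds_skipped=skipped,
    )


def axis_extreme_shapes(
    model: LDAModel, pca: PCAModel, k_sd: float, template: LVMesh | None = None
) -> tuple:
    """Shapes at -k_sd and +k_sd along a discriminant axis.

    The axis direction is the unit weight vector in standardized-coefficient
    space scaled so that a step of ``k_sd`` changes the Z-score by exactly
    ``k_sd``; the two extremes are symmetric about the mean shape.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    w_norm = float(np.linalg.norm(model.weights))
    if w_norm < 1e-15:
        raise ValueError("axis weights are zero")
    direction = np.zeros(pca.n_modes)
    direction[model.included_modes] = model.weights / w_norm
    step = k_sd * model.score_sd / w_norm  # standardized step giving dZ = k_sd
    raw_step = direction * step * pca.sd()  # raw (mm) coefficients per mode
    from .ssm import reconstruct

    minus = reconstruct(pca, -raw_step)
    plus = reconstruct(pca, raw_step)
    if template is None:
        return minus, plus
    return template.with_vector(minus), template.with_vector(plus)
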