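"""Point-distribution statistical shape model (Procrustes + PCA).

Corresponded meshes are pose-normalized by generalized Procrustes alignment
with translation and rotation only — scaling is deliberately excluded so that
ventricular size and length remain part of the shape signal and can load onto
the leading variation mode.  The aligned shape vectors feed a PCA computed by
singular value decomposition of the centred data matrix (numerically
equivalent to an eigendecomposition of the sample covariance, but stable when
the coordinate dimension vastly exceeds the number of subjects).

Coefficients are exposed both raw (mm along a unit mode) and standardized
(per-mode SD units); the standardized form is the interface to the
discriminant analysis and makes "±3 SD" shape synthesis well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh import LVMesh, TopologyError

__all__ = [
    "PCAModel",
    "ShapeCoefficients",
    "align_meshes",
    "align_to_reference",
    "fit_pca",
    "select_modes",
    "project",
    "reconstruct",
    "synthesize_extreme",
]

_GPA_TOL_MM = 1e-6
_GPA_MAX_ITER = 100


@dataclass
class PCAModel:
    """Mean shape, orthonormal variation modes and per-mode variances.

    ``modes`` has shape (3M, K) with orthonormal columns ordered by
    non-increasing variance (mm^2).  ``explained_ratio[k]`` is
    ``variances[k] / variances.sum()``.  ``n_modes_selected`` caches the
    result of :func:`select_modes` once the caller applies the cumulative
    variance rule.
    """

    mean_shape: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    explained_ratio: np.ndarray
    n_subjects: int
    topology_id: str = ""
    n_modes_selected: int | None = None

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def sd(self) -> np.ndarray:
        """Per-mode standard deviation (mm)."""
        return np.sqrt(self.variances)


@dataclass
class ShapeCoefficients:
    """Per-subject PCA scores; rows are subjects, columns modes.

    ``raw`` is in mm along each unit mode; ``standardized`` divides each
    column by the mode SD, so training-set columns have unit variance.
    """

    raw: np.ndarray
    variances: np.ndarray
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)

    @property
    def standardized(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.raw / np.sqrt(self.variances)[None, :]

    @property
    def n_subjects(self) -> int:
        return self.raw.shape[0]


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------
def align_meshes(meshes: list[LVMesh]) -> list[np.ndarray]:
    """Generalized Procrustes alignment (translation + rotation, no scaling).

    Every mesh is aligned to the evolving mean shape until the mean moves by
    less than 1e-6 mm per coordinate on average; the returned flattened shape
    vectors live in the frame of the converged mean.
    """
    if not meshes:
        raise ValueError("no meshes to align")
    topo = meshes[0].topology_id
    for m in meshes:
        if m.topology_id != topo:
            raise TopologyError("meshes do not share a topology")
    clouds = [m.as_points() for m in meshes]
    ref = clouds[0] - clouds[0].mean(axis=0)
    for _ in range(_GPA_MAX_ITER):
        aligned = [_procrustes_to(ref, c) for c in clouds]
        mean = np.mean(aligned, axis=0)
        mean -= mean.mean(axis=0)
        shift = float(np.mean(np.linalg.norm(mean - ref, axis=1)))
        ref = mean
        if shift < _GPA_TOL_MM:
            break
    aligned = [_procrustes_to(ref, c) for c in clouds]
    return [a.reshape(-1) for a in aligned]


def align_to_reference(mesh: LVMesh, reference: np.ndarray) -> np.ndarray:
    """Rigidly align one mesh to a reference shape vector (no scaling).

    Used to bring external subjects into the frame of a frozen shape model.
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    return _procrustes_to(ref, mesh.as_points()).reshape(-1)


def _procrustes_to(ref: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Least-squares rigid alignment of ``points`` onto ``ref`` (Kabsch)."""
    centred = points - points.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref, centred)
    return rot.apply(centred) + ref.mean(axis=0)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------
def fit_pca(vectors: list[np.ndarray], topology_id: str = "") -> PCAModel:
    """PCA of aligned shape vectors via SVD of the centred data matrix.

    Retains ``K = min(3M, n-1)`` modes.  Mode signs are fixed
    deterministically (the coordinate of largest absolute loading is made
    positive) and eigenvalue ties keep the SVD ordering, so repeated fits of
    the same data are bit-identical.
    """
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a shape model")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[1], n - 1)
    modes = vt[:k].T
    variances = (s[:k] ** 2) / (n - 1)
    # deterministic sign: largest-|loading| coordinate positive
    lead = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[lead, np.arange(k)])
    signs[signs == 0] = 1.0
    modes = modes * signs[None, :]
    total = variances.sum()
    ratio = variances / total if total > 0 else np.zeros_like(variances)
    return PCAModel(
        mean_shape=mean,
        modes=modes,
        variances=variances,
        explained_ratio=ratio,
        n_subjects=n,
        topology_id=topology_id,
    )


def select_modes(model: PCAModel, threshold: float = 0.90) -> int:
    """Smallest number of leading modes reaching the cumulative explained
    variance threshold (inclusive: hitting the threshold exactly qualifies)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cumulative = np.cumsum(model.explained_ratio)
    reached = np.flatnonzero(cumulative >= threshold - 1e-12)
    if reached.size == 0:
        raise ValueError("explained ratios never reach the threshold")
    k = int(reached[0]) + 1
    model.n_modes_selected = k
    return k


def project(model: PCAModel, vectors: np.ndarray, subject_ids=None) -> ShapeCoefficients:
    """Shape coefficients of one or many shape vectors.

    Raw score k is the inner product of ``x - mean`` with mode k (adjoint of
    reconstruction under orthonormality).
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[1] != model.mean_shape.size:
        raise ValueError(
            f"shape vector length {X.shape[1]} does not match model "
            f"({model.mean_shape.size})"
        )
    raw = (X - model.mean_shape) @ model.modes
    return ShapeCoefficients(raw=raw, variances=model.variances, subject_ids=subject_ids)


def reconstruct(model: PCAModel, raw: np.ndarray) -> np.ndarray:
    """Shape vector(s) from raw coefficients: mean + sum_k raw_k mode_k.

    Accepts fewer than K coefficients (truncated reconstruction)."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    k = raw.shape[1]
    if k > model.n_modes:
        raise ValueError("more coefficients than model modes")
    out = model.mean_shape[None, :] + raw @ model.modes[:, :k].T
    return out[0] if out.shape[0] == 1 else out


def synthesize_extreme(
    model: PCAModel,
    direction: np.ndarray,
    k_sd: float,
    template: LVMesh | None = None,
):
    """Shape at ``k_sd`` standard deviations along a direction in
    standardized-coefficient space.

    ``direction`` must be a unit vector (length up to K, zero-padded
    otherwise); raw coefficients are ``k_sd * direction_k * sd_k``.  Returns
    an :class:`LVMesh` when ``template`` provides the topology, else the bare
    shape vector.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be non-zero")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector in standardized space")
    if direction.size > model.n_modes:
        raise ValueError("direction has more components than model modes")
    raw = k_sd * direction * model.sd()[: direction.size]
    vec = reconstruct(model, raw)
    if template is None:
        return vec
    return template.with_vector(vec)
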