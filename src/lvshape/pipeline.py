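"""Study orchestration: groups, per-mode screening, LDA axes, reports.

``run_study`` executes the complete analysis on a cohort: (optional)
template personalization of masks, Procrustes alignment, PCA, selection of
the modes reaching 90% cumulative variance, per-mode two-sample t-tests, one
Fisher axis per requested comparison (rest obstruction, stress-only
obstruction, genotype) with resubstitution/leave-one-out AUC, Z-score tables
for every subject, and ±3 SD extreme anatomies with their AHA-17 thickness
profiles.  The rest axis additionally gets the two robustness variants: a
refit at the severe-obstruction 50 mmHg threshold and a refit on the paired
(rest+stress) subset, each summarized by the cosine of its angle to the main
axis direction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .discriminant import (
    LDAModel,
    ValidationReport,
    auc,
    axis_extreme_shapes,
    fit_lda,
    loo_cv_auc,
    zscore,
)
from .grouping import GroupAssignment, assign_groups
from .mesh import LVMesh, lvot_sector_area
from .personalize import FitConfig, aha17_map, fit_template, wall_thickness
from .ssm import (
    PCAModel,
    align_meshes,
    align_to_reference,
    fit_pca,
    project,
    select_modes,
)

__all__ = [
    "StudyConfig",
    "AxisResult",
    "StudyReport",
    "StageError",
    "compare_modes",
    "run_study",
    "project_external",
    "ExternalReport",
    "cohort_covariate_summary",
]

_AXIS_GROUPS = {
    "rest": ("R-", "R+"),
    "dstress": ("R-S-", "R-S+"),
    "gen": ("G-", "G+"),
}


class StageError(RuntimeError):
    """Pipeline failure labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Configuration of one full study run."""

    rest_threshold_mmHg: float = 30.0
    robustness_threshold_mmHg: float = 50.0
    variance_threshold: float = 0.90
    axes: tuple = ("rest", "dstress", "gen")
    paired_only: bool = False
    k_sd_extreme: float = 3.0
    shrinkage: str | float = "ledoit-wolf"
    bonferroni: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rest_threshold_mmHg <= 0 or self.robustness_threshold_mmHg <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must lie in (0, 1]")
        unknown = set(self.axes) - set(_AXIS_GROUPS)
        if unknown:
            raise ValueError(f"unknown axes {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AxisResult:
    """Everything computed for one remodelling axis."""

    name: str
    groups: tuple[str, str]
    model: LDAModel
    validation: ValidationReport
    zscores: np.ndarray  # all cohort subjects along this axis
    mode_stats: pd.DataFrame
    extreme_minus: LVMesh
    extreme_plus: LVMesh
    aha_minus: np.ndarray
    aha_plus: np.ndarray
    lvot_area_minus_mm2: float
    lvot_area_plus_mm2: float
    variants: dict = field(default_factory=dict)


@dataclass
class StudyReport:
    """In-memory result of :func:`run_study`."""

    config: StudyConfig
    assignment: GroupAssignment
    pca: PCAModel
    n_modes_selected: int
    coefficients: np.ndarray  # standardized, all subjects x all modes
    axes: dict
    fit_reports: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def zscore_table(self) -> pd.DataFrame:
        data = {"subject_id": self.assignment.subject_ids}
        data["rest_label"] = self.assignment.rest_label
        data["stress_label"] = [
            l if l is not None else "" for l in self.assignment.stress_label
        ]
        data["genotype"] = self.assignment.genotype
        for name, axis in self.axes.items():
            data[f"z_{name}"] = axis.zscores
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
def compare_modes(
    coeffs_a: np.ndarray,
    coeffs_b: np.ndarray,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Two-tailed two-sample Student's t-test per shape mode.

    Returns one row per mode with the t statistic, p-value and significance
    flag at ``alpha``.  No multiplicity correction is applied by default;
    ``bonferroni=True`` divides ``alpha`` by the number of modes.  Modes with
    zero pooled variance get p = 1 with a warning.
    """
    A = np.atleast_2d(np.asarray(coeffs_a, dtype=float))
    B = np.atleast_2d(np.asarray(coeffs_b, dtype=float))
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(A, B, axis=0, equal_var=True)
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)
    degenerate = ~np.isfinite(p_val)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} mode(s) with zero pooled variance; p set to 1",
            stacklevel=2,
        )
        t_stat[degenerate] = 0.0
        p_val[degenerate] = 1.0
    level = alpha / len(p_val) if bonferroni else alpha
    return pd.DataFrame(
        {
            "mode": np.arange(1, len(p_val) + 1),
            "t": t_stat,
            "p": p_val,
            "significant": p_val < level,
        }
    )


# --------------------------------------------------------------------------
def run_study(
    config: StudyConfig,
    records,
    meshes: list[LVMesh] | None = None,
    masks: list | None = None,
    template: LVMesh | None = None,
    out_dir: str | Path | None = None,
    fit_config: FitConfig | None = None,
) -> StudyReport:
    """Execute the full statistical shape analysis on one cohort.

    Provide either fitted ``meshes`` (one per record, shared topology) or
    raw binary ``masks`` plus a ``template`` to personalize first.  With
    ``out_dir`` set, models, tables, extreme meshes and a manifest are
    persisted there; all numeric outputs are deterministic for a fixed
    config, cohort and seed.
    """
    records = list(records)
    fit_reports: list = []
    if meshes is None:
        if masks is None or template is None:
            raise StageError("inputs", "need meshes, or masks plus a template")
        meshes = []
        for mask in masks:
            fitted, report = fit_template(mask, template, fit_config)
            meshes.append(fitted)
            fit_reports.append(report)
    if len(meshes) != len(records):
        raise StageError("inputs", "one mesh per cohort record required")

    try:
        assignment = assign_groups(records, config.rest_threshold_mmHg)
    except ValueError as exc:
        raise StageError("grouping", str(exc)) from exc

    try:
        vectors = align_meshes(meshes)
        pca = fit_pca(vectors, topology_id=meshes[0].topology_id)
        n_sel = select_modes(pca, config.variance_threshold)
    except ValueError as exc:
        raise StageError("shape-model", str(exc)) from exc
    coeffs = project(pca, np.asarray(vectors))
    std = coeffs.standardized
    included = np.arange(n_sel)
    template_mesh = meshes[0]

    axes: dict[str, AxisResult] = {}
    for axis_name in config.axes:
        neg_label, pos_label = _AXIS_GROUPS[axis_name]
        idx_neg = assignment.indices(neg_label)
        idx_pos = assignment.indices(pos_label)
        if len(idx_neg) < 3 or len(idx_pos) < 3:
            raise StageError(
                f"lda-{axis_name}",
                f"need >= 3 subjects per group, got {len(idx_neg)} {neg_label} "
                f"and {len(idx_pos)} {pos_label}",
            )
        axes[axis_name] = _fit_axis(
            axis_name, std, idx_neg, idx_pos, included, pca, template_mesh, config
        )

    if "rest" in axes:
        axes["rest"].variants.update(
            _rest_variants(config, records, assignment, std, included, axes["rest"])
        )

    report = StudyReport(
        config=config,
        assignment=assignment,
        pca=pca,
        n_modes_selected=n_sel,
        coefficients=std,
        axes=axes,
        fit_reports=fit_reports,
    )
    _genotype_projections(report)
    if out_dir is not None:
        _persist(report, Path(out_dir))
    return report


def _fit_axis(
    name, std, idx_neg, idx_pos, included, pca, template_mesh, config
) -> AxisResult:
    neg_label, pos_label = _AXIS_GROUPS[name]
    A = std[idx_neg][:, included]
    B = std[idx_pos][:, included]
    stats_df = compare_modes(A, B, bonferroni=config.bonferroni)
    try:
        model = fit_lda(
            A,
            B,
            included_modes=np.arange(len(included)),
            labels=(neg_label, pos_label),
            shrinkage=config.shrinkage,
        )
        # re-express over the full mode set for downstream projections
        model = LDAModel(
            weights=model.weights,
            included_modes=included,
            score_mean=model.score_mean,
            score_sd=model.score_sd,
            orientation_sign=model.orientation_sign,
            labels=model.labels,
            shrinkage=model.shrinkage,
        )
        labels_train = np.r_[np.zeros(len(A), bool), np.ones(len(B), bool)]
        validation = loo_cv_auc(
            np.vstack([A, B]),
            labels_train,
            shrinkage=config.shrinkage,
            threshold_mmHg=(
                config.rest_threshold_mmHg if name in ("rest", "dstress") else None
            ),
        )
    except ValueError as exc:
        raise StageError(f"lda-{name}", str(exc)) from exc

    z_all = zscore(model, std)
    minus, plus = axis_extreme_shapes(
        model, pca, config.k_sd_extreme, template=template_mesh
    )
    aha_minus = aha17_map(minus, wall_thickness(minus)).seg_thickness_mm
    aha_plus = aha17_map(plus, wall_thickness(plus)).seg_thickness_mm
    return AxisResult(
        name=name,
        groups=(neg_label, pos_label),
        model=model,
        validation=validation,
        zscores=z_all,
        mode_stats=stats_df,
        extreme_minus=minus,
        extreme_plus=plus,
        aha_minus=aha_minus,
        aha_plus=aha_plus,
        lvot_area_minus_mm2=lvot_sector_area(minus),
        lvot_area_plus_mm2=lvot_sector_area(plus),
    )


def _direction_cosine(model_a: LDAModel, model_b: LDAModel, n_modes: int) -> float:
    da = model_a.direction_standardized(n_modes)
    db = model_b.direction_standardized(n_modes)
    return float(np.dot(da, db))


def _rest_variants(config, records, assignment, std, included, rest_axis) -> dict:
    """Severe-threshold and paired-subset refits of the rest axis."""
    variants: dict[str, dict] = {}
    n_modes = std.shape[1]

    severe = assign_groups(records, config.robustness_threshold_mmHg)
    idx_neg = severe.indices("R-")
    idx_pos = severe.indices("R+")
    if len(idx_neg) >= 3 and len(idx_pos) >= 3:
        model = fit_lda(
            std[idx_neg][:, included],
            std[idx_pos][:, included],
            labels=("R-", "R+"),
            shrinkage=config.shrinkage,
        )
        model.included_modes = included
        variants["severe_threshold"] = {
            "threshold_mmHg": config.robustness_threshold_mmHg,
            "n_per_group": (len(idx_neg), len(idx_pos)),
            "direction_cosine_vs_rest": _direction_cosine(
                model, rest_axis.model, n_modes
            ),
        }
    else:
        warnings.warn("severe-threshold variant skipped: groups too small")

    paired = [
        i
        for i, r in enumerate(records)
        if getattr(r, "drop_stress_mmHg", None) is not None
    ]
    rest_of = {i: l for i, l in enumerate(assignment.rest_label)}
    idx_neg = [i for i in paired if rest_of[i] == "R-"]
    idx_pos = [i for i in paired if rest_of[i] == "R+"]
    if len(idx_neg) >= 3 and len(idx_pos) >= 3:
        model = fit_lda(
            std[idx_neg][:, included],
            std[idx_pos][:, included],
            labels=("R-", "R+"),
            shrinkage=config.shrinkage,
        )
        model.included_modes = included
        variants["paired_subset"] = {
            "n_per_group": (len(idx_neg), len(idx_pos)),
            "direction_cosine_vs_rest": _direction_cosine(
                model, rest_axis.model, n_modes
            ),
        }
    else:
        warnings.warn("paired-subset variant skipped: groups too small")
    return variants


def _genotype_projections(report: StudyReport) -> None:
    """Mean Z of the genotype strata on every fitted axis."""
    assignment = report.assignment
    for axis in report.axes.values():
        proj = {}
        for label in ("G-", "G+"):
            idx = assignment.indices(label)
            if idx:
                proj[label] = float(np.mean(axis.zscores[idx]))
        axis.variants["genotype_mean_z"] = proj


# --------------------------------------------------------------------------
# external projection
# --------------------------------------------------------------------------
@dataclass
class ExternalReport:
    """Frozen-model evaluation on an external cohort."""

    auc: float
    zscores: np.ndarray
    n_per_group: tuple[int, int]


def project_external(
    pca: PCAModel,
    axis: LDAModel,
    external_meshes: list[LVMesh] | None,
    external_labels,
    external_vectors: np.ndarray | None = None,
) -> ExternalReport:
    """Score an external cohort through a frozen PCA and LDA.

    External meshes must share the training topology; each is rigidly
    aligned (no scaling) to the model's mean shape, projected, and Z-scored
    without any refitting.  Pre-aligned shape vectors can be passed directly
    via ``external_vectors``.
    """
    if external_vectors is None:
        if external_meshes is None:
            raise ValueError("provide external meshes or vectors")
        for m in external_meshes:
            if m.as_vector().size != pca.mean_shape.size:
                raise ValueError("external mesh topology does not match model")
        external_vectors = np.asarray(
            [align_to_reference(m, pca.mean_shape) for m in external_meshes]
        )
    coeffs = project(pca, external_vectors)
    z = zscore(axis, coeffs.standardized)
    y = np.asarray(external_labels, dtype=bool)
    return ExternalReport(
        auc=auc(z, y),
        zscores=z,
        n_per_group=(int((~y).sum()), int(y.sum())),
    )


# --------------------------------------------------------------------------
# optional cohort covariate description
# --------------------------------------------------------------------------
def cohort_covariate_summary(records, rest_threshold_mmHg: float = 30.0) -> pd.DataFrame:
    """Thin descriptive comparison of rest pressure drops and genotype
    between R- and R+ (normality check, Mann-Whitney U, chi-squared)."""
    assignment = assign_groups(records, rest_threshold_mmHg)
    drops = np.asarray([float(r.drop_rest_mmHg) for r in records])
    neg = drops[assignment.indices("R-")]
    pos = drops[assignment.indices("R+")]
    rows = []
    for name, values in (("R-", neg), ("R+", pos)):
        sw_p = stats.shapiro(values).pvalue if 3 <= len(values) <= 5000 else np.nan
        rows.append(
            {
                "group": name,
                "n": len(values),
                "drop_rest_median_mmHg": float(np.median(values)),
                "drop_rest_iqr_mmHg": float(
                    np.subtract(*np.percentile(values, [75, 25]))
                ),
                "shapiro_p": sw_p,
            }
        )
    summary = pd.DataFrame(rows)
    if len(neg) and len(pos):
        summary.attrs["mannwhitney_p"] = float(
            stats.mannwhitneyu(neg, pos).pvalue
        )
    geno = pd.crosstab(
        pd.Series(assignment.rest_label, name="rest"),
        pd.Series(assignment.genotype, name="genotype"),
    )
    if geno.shape == (2, 2):
        summary.attrs["chi2_genotype_p"] = float(
            stats.chi2_contingency(geno.values).pvalue
        )
    return summary


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------
def _persist(report: StudyReport, out_dir: Path) -> None:
    from . import io as lvio

    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    path = out_dir / "shape_model.h5"
    lvio.save_pca_h5(report.pca, path)
    written.append(path)

    path = out_dir / "coefficients.csv"
    pd.DataFrame(
        report.coefficients,
        index=pd.Index(report.assignment.subject_ids, name="subject_id"),
        columns=[f"mode_{k + 1}" for k in range(report.coefficients.shape[1])],
    ).to_csv(path, float_format="%.10g")
    written.append(path)

    path = out_dir / "zscores.csv"
    report.zscore_table().to_csv(path, index=False, float_format="%.10g")
    written.append(path)

    for name, axis in report.axes.items():
        base = out_dir / f"axis_{name}"
        lvio.save_lda_h5(axis.model, base.with_suffix(".h5"))
        written.append(base.with_suffix(".h5"))
        axis.mode_stats.to_csv(
            out_dir / f"axis_{name}_mode_stats.csv", index=False, float_format="%.10g"
        )
        written.append(out_dir / f"axis_{name}_mode_stats.csv")
        aha = pd.DataFrame(
            {
                "segment": np.arange(1, 18),
                "thickness_minus_mm": axis.aha_minus,
                "thickness_plus_mm": axis.aha_plus,
            }
        )
        aha.to_csv(
            out_dir / f"axis_{name}_aha17.csv", index=False, float_format="%.10g"
        )
        written.append(out_dir / f"axis_{name}_aha17.csv")
        for side, mesh in (("minus", axis.extreme_minus), ("plus", axis.extreme_plus)):
            mesh_path = out_dir / f"axis_{name}_extreme_{side}.ply"
            lvio.save_mesh_ply(mesh, mesh_path)
            written.append(mesh_path)
        val = dataclasses.asdict(axis.validation)
        val["variants"] = _jsonable(axis.variants)
        val_path = out_dir / f"axis_{name}_validation.json"
        val_path.write_text(json.dumps(val, indent=1, sort_keys=True))
        written.append(val_path)

    if report.fit_reports:
        fits = pd.DataFrame([dataclasses.asdict(r) for r in report.fit_reports])
        fits.insert(0, "subject_id", report.assignment.subject_ids)
        fits.to_csv(out_dir / "fit_reports.csv", index=False, float_format="%.10g")
        written.append(out_dir / "fit_reports.csv")

    config_dict = report.config.to_dict()
    manifest = {
        "package": "lvshape",
        "version": __version__,
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_subjects": len(report.assignment.subject_ids),
        "n_modes_selected": report.n_modes_selected,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report.manifest = manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
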