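"""Parametric synthetic LV anatomies and cohort generation.

This module fabricates the inputs the analysis pipeline expects from a real
imaging study: corresponded endo/epi surface meshes, and a cohort table with
LVOT peak pressure drops (rest and stress) and genotype labels.

The geometric model is a truncated semi-ellipsoidal cavity with a wall whose
thickness field carries a localized septal bump (optionally spiralling from
base to apex), plus an inward displacement of both surfaces in the basal
anteroseptal LVOT sector.  Those four controllable features — basal septal
hypertrophy, LV lengthening, apical dilatation and LVOT inward remodelling —
are the anatomical components of the obstructive-HCM remodelling signature
that the statistical machinery downstream is supposed to recover.

Pressure-drop labels follow the simplified Bernoulli relation
``dP = 4 v^2`` (mmHg, v in m/s), with the subject's LVOT velocity scaled by
flow continuity from the effective outflow-sector area and perturbed with
lognormal measurement noise.  A per-subject stress multiplier creates the
"obstructive only at stress" stratum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .mesh import LVMesh, lvot_sector_area, lvot_sector_radius, wrap_angle

__all__ = [
    "LVGeometryParams",
    "PopulationSpec",
    "SubjectRecord",
    "Subject",
    "InvalidGeometryError",
    "generate_lv_surface",
    "thickness_field",
    "bernoulli_pressure_drop",
    "lvot_velocity",
    "sample_cohort",
    "cohort_table",
    "deformation_study_spec",
    "default_population_spec",
]


class InvalidGeometryError(ValueError):
    """Raised when parameters yield a self-intersecting or degenerate wall."""


@dataclass
class LVGeometryParams:
    """Generative parameters of one synthetic left ventricle.

    All lengths in mm, angles in radians.  ``septal_bump_center`` is
    ``(theta_s, u_s)`` — the angular position and longitudinal fraction of the
    peak of the septal thickness bump; ``septal_bump_width`` is the pair of
    Gaussian widths ``(sigma_theta, sigma_u)`` shared by the septal bump and
    the LVOT inward-remodelling field.
    """

    length_mm: float = 80.0
    endo_base_radius_mm: float = 24.0
    base_thickness_mm: float = 8.0
    septal_bump_amp_mm: float = 5.0
    septal_bump_center: tuple[float, float] = (0.2, 0.25)
    septal_bump_width: tuple[float, float] = (0.55, 0.18)
    spiral_drift_rad: float = 0.0
    apical_dilation: float = 0.08
    lvot_inward_mm: float = 0.0
    sphericity_exp: float = 2.0

    def validate(self) -> None:
        if self.length_mm <= 0:
            raise InvalidGeometryError("length_mm must be positive")
        if self.endo_base_radius_mm <= 0:
            raise InvalidGeometryError("endo_base_radius_mm must be positive")
        if self.base_thickness_mm <= 0:
            raise InvalidGeometryError("base_thickness_mm must be positive")
        if min(self.septal_bump_width) <= 0:
            raise InvalidGeometryError("bump widths must be positive")
        if self.apical_dilation < 0:
            raise InvalidGeometryError("apical_dilation must be >= 0")
        if self.lvot_inward_mm < 0:
            raise InvalidGeometryError("lvot_inward_mm must be >= 0")
        if self.sphericity_exp <= 0:
            raise InvalidGeometryError("sphericity_exp must be positive")


@dataclass
class PopulationSpec:
    """Two-group synthetic study design.

    ``group_param_means``/``group_param_sds`` hold one
    :class:`LVGeometryParams` per group; SD objects carry per-field standard
    deviations (tuples component-wise).  ``velocity_ref_m_s`` is the LVOT
    velocity of an unremodelled outflow tract; per-subject velocities scale
    with the inverse effective LVOT sector area (flow continuity) and are
    multiplied by lognormal noise with coefficient of variation
    ``velocity_noise_cv``.  ``stress_test_fraction`` controls how many
    subjects carry a stress measurement (the rest have it missing).
    """

    n_per_group: int = 60
    group_param_means: tuple[LVGeometryParams, LVGeometryParams] = field(
        default_factory=lambda: (LVGeometryParams(), LVGeometryParams())
    )
    group_param_sds: tuple[LVGeometryParams, LVGeometryParams] = field(
        default_factory=lambda: (
            _zero_sds(),
            _zero_sds(),
        )
    )
    velocity_ref_m_s: float = 1.5
    velocity_noise_cv: float = 0.0
    genotype_positive_fraction: tuple[float, float] = (0.5, 0.5)
    stress_test_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for f in self.genotype_positive_fraction:
            if not 0.0 <= f <= 1.0:
                raise ValueError("genotype fractions must lie in [0, 1]")
        if not 0.0 <= self.stress_test_fraction <= 1.0:
            raise ValueError("stress_test_fraction must lie in [0, 1]")
        if self.velocity_noise_cv < 0:
            raise ValueError("velocity_noise_cv must be >= 0")
        for sds in self.group_param_sds:
            for name, value in _iter_scalar_fields(sds):
                if value < 0:
                    raise ValueError(f"negative SD for field {name}")


@dataclass
class SubjectRecord:
    """Cohort-table row: pressure-drop labels and genotype for one subject."""

    subject_id: str
    drop_rest_mmHg: float
    drop_stress_mmHg: float | None = None
    genotype: str = "unknown"
    group: str = "unassigned"


@dataclass
class Subject:
    """One synthetic subject: generative truth, anatomy and labels."""

    params: LVGeometryParams
    mesh: LVMesh
    record: SubjectRecord


def _zero_sds() -> LVGeometryParams:
    """An LVGeometryParams object whose every scalar is 0 (used as SDs)."""
    return LVGeometryParams(
        length_mm=0.0,
        endo_base_radius_mm=0.0,
        base_thickness_mm=0.0,
        septal_bump_amp_mm=0.0,
        septal_bump_center=(0.0, 0.0),
        septal_bump_width=(0.0, 0.0),
        spiral_drift_rad=0.0,
        apical_dilation=0.0,
        lvot_inward_mm=0.0,
        sphericity_exp=0.0,
    )


def _iter_scalar_fields(params: LVGeometryParams):
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if isinstance(value, tuple):
            for k, v in enumerate(value):
                yield f"{f.name}[{k}]", float(v)
        else:
            yield f.name, float(value)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------
def _radius_profile(params: LVGeometryParams, u: np.ndarray) -> np.ndarray:
    """Endocardial radius r(u) of the (pre-LVOT) surface of revolution."""
    s = params.sphericity_exp
    core = np.sqrt(np.clip(1.0 - u**s, 0.0, None))
    return params.endo_base_radius_mm * core * (1.0 + params.apical_dilation * u**2)


def _radius_profile_derivative(params: LVGeometryParams, u: np.ndarray) -> np.ndarray:
    """dr/du of the endocardial profile (diverges at u=1; caller handles apex)."""
    s = params.sphericity_exp
    r0 = params.endo_base_radius_mm
    d = params.apical_dilation
    core = np.sqrt(np.clip(1.0 - u**s, 1e-12, None))
    dcore = -0.5 * s * u ** (s - 1.0) / core
    return r0 * (dcore * (1.0 + d * u**2) + core * 2.0 * d * u)


def thickness_field(params: LVGeometryParams, theta: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Wall thickness t(theta, u): baseline plus the Gaussian septal bump.

    ``theta`` (n_circ,) and ``u`` (n_long,) are grid coordinates; the bump
    centre drifts circumferentially by ``spiral_drift_rad`` per unit ``u``.
    Returns an (n_long, n_circ) array in mm.
    """
    theta_s, u_s = params.septal_bump_center
    sig_t, sig_u = params.septal_bump_width
    uu = u[:, None]
    centre = theta_s + params.spiral_drift_rad * uu
    dtheta = wrap_angle(theta[None, :] - centre)
    bump = np.exp(
        -(dtheta**2) / (2.0 * sig_t**2) - (uu - u_s) ** 2 / (2.0 * sig_u**2)
    )
    return params.base_thickness_mm + params.septal_bump_amp_mm * bump


def generate_lv_surface(
    params: LVGeometryParams, n_circ: int = 64, n_long: int = 32
) -> LVMesh:
    """Build the corresponded endo+epi surface grid for one parameter set.

    The endocardium is a surface of revolution closed at the apex; the
    epicardium is the endocardium offset outward along its unit normals by the
    thickness field; finally both surfaces are displaced radially inward in
    the basal anteroseptal sector by the LVOT remodelling field.  Node
    ``(i, j)`` sits at ``(u_i, theta_j)`` for every parameter set, so meshes
    generated with different parameters are in correspondence by construction.
    """
    if n_circ < 16 or n_long < 8:
        raise ValueError("require n_circ >= 16 and n_long >= 8")
    params.validate()

    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    u = np.linspace(0.0, 1.0, n_long)
    L = params.length_mm

    r = _radius_profile(params, u)  # (n_long,)
    z = -u * L
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    endo = np.empty((n_long, n_circ, 3))
    endo[..., 0] = r[:, None] * cos_t[None, :]
    endo[..., 1] = r[:, None] * sin_t[None, :]
    endo[..., 2] = z[:, None]

    # analytic outward normal of the surface of revolution:
    # meridian tangent (dr/du, -L) -> outward normal prop. to (L, dr/du)
    drdu = _radius_profile_derivative(params, u)
    norm = np.hypot(L, drdu)
    n_r = L / norm
    n_z = drdu / norm
    n_r[-1], n_z[-1] = 0.0, -1.0  # apex: profile derivative diverges
    normal = np.empty_like(endo)
    normal[..., 0] = n_r[:, None] * cos_t[None, :]
    normal[..., 1] = n_r[:, None] * sin_t[None, :]
    normal[..., 2] = np.broadcast_to(n_z[:, None], (n_long, n_circ))

    t_field = thickness_field(params, theta, u)
    if np.min(t_field) <= 0.0:
        raise InvalidGeometryError("thickness field non-positive (epi meets endo)")
    epi = endo + t_field[..., None] * normal

    # LVOT inward remodelling: radial displacement of both surfaces in the
    # fixed anteroseptal sector (centred on theta = 0, decaying from the base)
    if params.lvot_inward_mm > 0.0:
        sig_t, sig_u = params.septal_bump_width
        g = params.lvot_inward_mm * np.exp(
            -(wrap_angle(theta)[None, :] ** 2) / (2.0 * sig_t**2)
            - (u[:, None] ** 2) / (2.0 * sig_u**2)
        )
        disp = np.empty((n_long, n_circ, 3))
        disp[..., 0] = g * cos_t[None, :]
        disp[..., 1] = g * sin_t[None, :]
        disp[..., 2] = 0.0
        endo = endo - disp
        epi = epi - disp
        r_after = np.hypot(endo[..., 0], endo[..., 1])
        if np.min(r_after[:-1]) <= 0.0:
            raise InvalidGeometryError("LVOT displacement collapses the cavity")

    mesh = LVMesh(endo_points=endo, epi_points=epi, node_theta=theta, node_u=u)
    gap = np.linalg.norm(mesh.epi_points - mesh.endo_points, axis=2)
    if np.min(gap) <= 0.0:
        raise InvalidGeometryError("epicardium touches endocardium")
    return mesh


# --------------------------------------------------------------------------
# haemodynamic labels
# --------------------------------------------------------------------------
def bernoulli_pressure_drop(velocity_m_s: float) -> float:
    """Simplified Bernoulli pressure drop: dP = 4 v^2 (mmHg, v in m/s)."""
    velocity = np.asarray(velocity_m_s, dtype=float)
    if np.any(velocity < 0):
        raise ValueError("velocity must be non-negative")
    result = 4.0 * velocity**2
    return float(result) if np.isscalar(velocity_m_s) else result


def lvot_velocity(v_ref_m_s: float, area_ref_mm2: float, area_mm2: float) -> float:
    """Flow-continuity velocity scaling: v = v_ref * (A_ref / A)."""
    if area_mm2 <= 0 or area_ref_mm2 <= 0:
        raise ValueError("areas must be positive")
    return float(v_ref_m_s * area_ref_mm2 / area_mm2)


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------
_MAX_DRAW_RETRIES = 25


def _draw_params(
    rng: np.random.Generator, means: LVGeometryParams, sds: LVGeometryParams
) -> LVGeometryParams:
    """Truncated-normal (+-3 SD) draw of every scalar field."""
    values: dict[str, object] = {}
    for f in dataclasses.fields(means):
        mu = getattr(means, f.name)
        sd = getattr(sds, f.name)
        if isinstance(mu, tuple):
            values[f.name] = tuple(
                _trunc_draw(rng, float(m), float(s)) for m, s in zip(mu, sd)
            )
        else:
            values[f.name] = _trunc_draw(rng, float(mu), float(sd))
    # hard physical floors irrespective of the draw
    values["lvot_inward_mm"] = max(0.0, values["lvot_inward_mm"])
    values["apical_dilation"] = max(0.0, values["apical_dilation"])
    return LVGeometryParams(**values)


def _trunc_draw(rng: np.random.Generator, mu: float, sd: float) -> float:
    if sd == 0.0:
        return mu
    return float(
        stats.truncnorm.rvs(-3.0, 3.0, loc=mu, scale=sd, random_state=rng)
    )


def sample_cohort(spec: PopulationSpec) -> list[Subject]:
    """Draw a fully reproducible two-group synthetic cohort.

    Per subject: geometry parameters from the group's truncated-normal field
    distributions; LVOT velocity from flow continuity against the same
    anatomy with the inward remodelling removed, times lognormal measurement
    noise; rest and stress pressure drops via the Bernoulli relation with a
    per-subject stress multiplier ``kappa = 1 + |N(0.4, 0.2)|``; genotype by
    the group's positive fraction.  A single seeded RNG stream and a fixed
    subject order make the output byte-reproducible.
    """
    from .grouping import classify_record

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cv = spec.velocity_noise_cv
    sigma_log = float(np.sqrt(np.log1p(cv * cv)))

    subjects: list[Subject] = []
    idx = 0
    for g, (means, sds) in enumerate(zip(spec.group_param_means, spec.group_param_sds)):
        for _ in range(spec.n_per_group):
            mesh = None
            for _attempt in range(_MAX_DRAW_RETRIES):
                params = _draw_params(rng, means, sds)
                try:
                    mesh = generate_lv_surface(params)
                    break
                except InvalidGeometryError:
                    continue
            if mesh is None:
                raise InvalidGeometryError(
                    f"could not draw a valid geometry for group {g} within "
                    f"{_MAX_DRAW_RETRIES} attempts"
                )

            # effective outflow-sector area vs the unremodelled reference
            ref_params = dataclasses.replace(params, lvot_inward_mm=0.0)
            ref_mesh = generate_lv_surface(ref_params)
            area = lvot_sector_area(mesh)
            area_ref = lvot_sector_area(ref_mesh)
            v = lvot_velocity(spec.velocity_ref_m_s, area_ref, area)
            if sigma_log > 0.0:
                v *= float(
                    np.exp(rng.normal(-0.5 * sigma_log**2, sigma_log))
                )
            kappa = 1.0 + abs(rng.normal(0.4, 0.2))
            drop_rest = bernoulli_pressure_drop(v)
            has_stress = rng.random() < spec.stress_test_fraction
            drop_stress = bernoulli_pressure_drop(kappa * v) if has_stress else None
            genotype = (
                "G+" if rng.random() < spec.genotype_positive_fraction[g] else "G-"
            )
            record = SubjectRecord(
                subject_id=f"S{idx:04d}",
                drop_rest_mmHg=round(drop_rest, 6),
                drop_stress_mmHg=(
                    round(drop_stress, 6) if drop_stress is not None else None
                ),
                genotype=genotype,
            )
            record.group = classify_record(record)
            subjects.append(Subject(params=params, mesh=mesh, record=record))
            idx += 1
    return subjects


def cohort_table(subjects: list[Subject]):
    """Cohort CSV schema as a DataFrame (missing stress left empty)."""
    import pandas as pd

    rows = []
    for s in subjects:
        r = s.record
        rows.append(
            {
                "subject_id": r.subject_id,
                "drop_rest_mmHg": r.drop_rest_mmHg,
                "drop_stress_mmHg": r.drop_stress_mmHg,
                "genotype": r.genotype,
                "group": r.group,
            }
        )
    return pd.DataFrame(rows)


def deformation_study_spec(n_per_group: int = 200, seed: int = 21) -> PopulationSpec:
    """Two groups differing along a known deformation, for recovery studies.

    Group 1 equals group 0 shifted by +3 mm of septal bump amplitude and
    +3 mm of LVOT inward remodelling; every nuisance SD is at most half the
    effect size, so the discriminant direction fitted to this cohort can be
    compared against the generative deformation itself.
    """
    base = LVGeometryParams(
        septal_bump_amp_mm=5.0, lvot_inward_mm=0.5, spiral_drift_rad=0.0
    )
    shifted = dataclasses.replace(
        base, septal_bump_amp_mm=8.0, lvot_inward_mm=3.5
    )
    sds = LVGeometryParams(
        length_mm=1.5,
        endo_base_radius_mm=0.75,
        base_thickness_mm=0.5,
        septal_bump_amp_mm=1.0,
        septal_bump_center=(0.06, 0.025),
        septal_bump_width=(0.03, 0.015),
        spiral_drift_rad=0.05,
        apical_dilation=0.02,
        lvot_inward_mm=1.0,
        sphericity_exp=0.08,
    )
    return PopulationSpec(
        n_per_group=n_per_group,
        group_param_means=(base, shifted),
        group_param_sds=(sds, sds),
        seed=seed,
    )


def default_population_spec(
    n_per_group: int = 60, seed: int = 0
) -> PopulationSpec:
    """The canonical obstructive-remodelling study design.

    Group 0 emulates non-obstructive HCM (modest septal bump, open outflow
    tract); group 1 emulates the obstructive phenotype (larger, spiralling
    septal bump, apical dilatation, longer ventricle and inward LVOT
    remodelling).  Velocity reference and noise are chosen so that the two
    groups straddle the 30 mmHg rest threshold with realistic overlap rather
    than separating deterministically; genotype-positive subjects are less
    frequent in the obstructive group, giving G- cases the more obstructive
    anatomy on average.
    """
    non_obstructive = LVGeometryParams(
        length_mm=78.0,
        endo_base_radius_mm=24.0,
        base_thickness_mm=8.0,
        septal_bump_amp_mm=5.0,
        septal_bump_center=(0.2, 0.25),
        septal_bump_width=(0.55, 0.18),
        spiral_drift_rad=0.05,
        apical_dilation=0.06,
        lvot_inward_mm=0.5,
        sphericity_exp=2.0,
    )
    obstructive = LVGeometryParams(
        length_mm=83.0,
        endo_base_radius_mm=24.0,
        base_thickness_mm=8.5,
        septal_bump_amp_mm=8.0,
        septal_bump_center=(0.2, 0.25),
        septal_bump_width=(0.55, 0.18),
        spiral_drift_rad=0.35,
        apical_dilation=0.16,
        lvot_inward_mm=4.0,
        sphericity_exp=2.0,
    )
    sds_common = LVGeometryParams(
        length_mm=4.0,
        endo_base_radius_mm=1.5,
        base_thickness_mm=1.0,
        septal_bump_amp_mm=1.2,
        septal_bump_center=(0.15, 0.06),
        septal_bump_width=(0.08, 0.04),
        spiral_drift_rad=0.15,
        apical_dilation=0.05,
        lvot_inward_mm=0.4,
        sphericity_exp=0.20,
    )
    sds_obstructive = dataclasses.replace(sds_common, lvot_inward_mm=1.2)
    return PopulationSpec(
        n_per_group=n_per_group,
        group_param_means=(non_obstructive, obstructive),
        group_param_sds=(sds_common, sds_obstructive),
        velocity_ref_m_s=2.1,
        velocity_noise_cv=0.15,
        genotype_positive_fraction=(0.45, 0.25),
        stress_test_fraction=0.7,
        seed=seed,
    )
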