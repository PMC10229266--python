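# Methods

## Scientific problem

In hypertrophic cardiomyopathy (HCM), dynamic left-ventricular outflow tract
obstruction (LVOTO) is graded by the Doppler-derived peak pressure drop,
ΔP = 4v² (mmHg, v in m/s), with ≥30 mmHg at rest or stress defining the
obstructive phenotype and ≥50 mmHg severe obstruction.  The anatomy behind
the gradient — basal septal hypertrophy, inward remodelling of the
anteroseptal outflow tract, apical dilatation, ventricular lengthening — is
distributed over the whole chamber and poorly captured by single
measurements.  This package represents each LV as a corresponded surface
mesh, learns the population's shape variation by PCA, and condenses the
obstructive/non-obstructive anatomical difference into Fisher discriminant
axes whose per-subject coordinate (Z-score) is a continuous remodelling
score.

## Anatomical frame and mesh representation

All meshes share a fixed grid: endocardial and epicardial surfaces sampled
at `n_long × n_circ` (default 32 × 64) nodes indexed by longitudinal
fraction u ∈ [0, 1] (base → apex) and circumferential angle θ.  The long
axis is z (base at z = 0, apex below); θ = 0 marks the centre of the
anteroseptal LVOT sector and increases counter-clockwise viewed from the
apex, matching the AHA bull's-eye convention.  The septum occupies a fixed
120° sector centred on θ = 0; the LVOT sector used for effective
outflow-area computations is the basal third (u < 1/3) within ±30° of θ = 0,
and its effective area is modelled as a 60° circular sector of the
sector-mean endocardial radius.  Correspondence across subjects is by grid
construction (generator) or by fitting one shared template (real masks);
node (i, j) always denotes the same anatomical location.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not the full complexity of HCM anatomy:

* **Endocardium** — surface of revolution
  r(u) = R_base · (1 − u^s)^{1/2} · (1 + d_ap u²), z = −uL, closed at the
  apex.  `sphericity_exp` s = 2 gives a semi-ellipsoid; `apical_dilation`
  d_ap widens the apical third.
* **Wall** — the epicardium is the endocardium offset along its outward
  normals by t(θ, u) = t₀ + A_sept · exp(−Δθ²/2σ_θ² − (u−u_s)²/2σ_u²), a
  Gaussian septal bump whose centre may drift circumferentially with depth
  (`spiral_drift_rad`), emulating spiral hypertrophy patterns.
* **LVOT inward remodelling** — both surfaces are displaced radially inward
  by A_lvot · exp(−θ²/2σ_θ² − u²/2σ_u²) in the anteroseptal sector (the
  widths are shared with the septal bump, keeping the parameter count low).
* **Labels** — per-subject LVOT velocity follows flow continuity,
  v = v_ref · (A_ref/A_sector), where A_ref is the same anatomy with the
  inward remodelling removed; a lognormal factor (CV 0.15, in the range of
  Doppler peak-velocity repeatability) models measurement noise, and
  ΔP = 4v².  Stress drops use a per-subject multiplier κ = 1 + |N(0.4, 0.2)|,
  creating a stratum obstructive only at stress.  Genotype is sampled per
  group with the positive fraction lower in the obstructive group, so
  genotype-negative subjects carry the more obstructive anatomy on average.

Default two-group design (`default_population_spec`): 60 subjects/group;
non-obstructive group with a 5 mm septal bump and open outflow tract versus
an obstructive group with an 8 mm spiralling bump, 4 mm inward LVOT
remodelling, longer ventricle and more apical dilatation; v_ref = 2.1 m/s.
These values put ~20–35% of the cohort above the 30 mmHg rest threshold and
make obstruction statistically—not deterministically—predictable from
anatomy, which is the regime the discriminant analysis is designed for.
Parameters are drawn per field from ±3 SD truncated normals with bounded
retries; one seeded RNG stream and fixed subject order make cohorts
byte-reproducible.

What the generator does **not** model: mitral valve and papillary anatomy,
trabeculation, torsion/motion, image intensities (only segmentations), and
the high-dimensional residual variation of real populations (its shape
spectrum has ~13 latent factors, so "90% variance" is reached within a
handful of modes rather than ~25).  Passing tests therefore demonstrate the
correctness and calibration of the machinery under known truth, not
clinical performance on real CMR.

## Voxelization and contours

A voxel belongs to the myocardium when its centre lies between the two
surfaces; containment is evaluated radially per meridian (exact for the
star-shaped cross-sections generated here).  The slice stack covers the
full long-axis extent (`ceil(extent / slice_mm)` slices, base first), with
defaults 2 mm in-plane / 8 mm slices, typical of short-axis cine CMR.
Contours are recovered from mask boundaries by marching squares; outer
boundaries are epicardial, enclosed ones endocardial.  Contours shorter
than 8 points are discarded; an interior slice losing every boundary raises
a resolution error.

## Template personalization

A population-neutral template (smooth 9 mm wall, no bump/dilatation) is
mapped onto each mask in two stages.  Initialization estimates the base
plane and cavity length from the contour stack (each end extends half a
slice beyond the extreme contour planes) and maps the template's
longitudinal parametrization affinely onto that span; the in-plane axis and
scale come from the epicardial boundary centroid and RMS radius.  The long
axis is assumed along the slice normal (short-axis convention), and the
circumferential origin is inherited from the world frame — rotational
correspondence across subjects therefore relies on a consistent patient
orientation, which the generator provides and which a real study would
obtain from anatomical landmarks.  Iteration then alternates normal
projection (each node moves along its normal by the normal component of the
offset to the nearest boundary point of the matching surface) with grid
Laplacian smoothing (weight λ = 0.3), stopping when the mean nodal
displacement falls below 0.05 mm (max 100 iterations; non-convergence is
flagged, not fatal).  On CMR-resolution voxelizations of known anatomies
the mean surface-to-contour error is ≈0.2 mm, comfortably below the
half-in-plane-resolution regime reported for template fitting on real
segmentations; real contours would add observer variability not present
here.

Wall thickness is measured by casting each endocardial node's normal ray
against the epicardial triangulation and vice versa, averaging where both
intersect (NaN where neither does, excluded from segment means).  AHA-17
aggregation uses longitudinal thirds for basal/mid/apical rings, 60°
sectors (basal/mid), 90° sectors (apical) and the collapsed apex row as
segment 17.

## Shape model

Generalized Procrustes alignment uses translation and rotation only — size
is genuine disease signal (the leading mode of real HCM cohorts mixes size
and length), so scaling is never removed.  PCA is computed by SVD of the
centred data matrix (equivalent to the covariance eigendecomposition,
stable at 3M ≫ n); K = min(3M, n−1) modes are retained, signs fixed by
making the largest-magnitude loading positive, ties kept in SVD order —
repeated fits are bit-identical.  The mode-count rule takes the smallest K′
whose cumulative explained variance reaches the threshold (default 0.90,
inclusive at the boundary).  Coefficients are used standardized (per-mode
SD units), which makes "±3 SD" synthesis and Z-scores well defined.

## Discriminant axes

For each comparison (R−/R+ at rest; R−S−/R−S+ for stress-only obstruction;
G−/G+ for genotype) the axis is w ∝ S_w⁻¹(μ_B − μ_A) over the selected
modes.  S_w is the pooled within-class covariance with Ledoit–Wolf
shrinkage by default: with a couple of dozen modes and potentially small
strata the empirical scatter can be ill-conditioned, and Ledoit–Wolf is
parameter-free and scale-equivariant (Z-scores are invariant to rescaling
all coefficients).  A fixed shrinkage intensity, or 0 with a fallback ridge
on numerically singular scatter, can be requested instead.  Z-scores
normalize the discriminant score by the pooled training mean/SD, oriented
so the obstructive-like (or G+) group has the higher mean; only the
continuous Z is used, never a hard threshold (equal priors, no
classification rule).  Leave-one-out refits the discriminant and its
normalization per fold but keeps the PCA basis frozen, mirroring a
shape-atlas workflow where the atlas is a fixed reference.  AUC uses the
Mann–Whitney formulation with ties counted one half.

Axis extremes at ±k SD step along the unit weight direction in standardized
space, scaled so the step changes Z by exactly k; the two extremes are
symmetric about the mean shape.  When the axis is trained on the full PCA
population the mean shape has Z ≈ 0 and the extremes re-project to ±k.

## Numerical choices and degenerate inputs

* Ray casting and point-to-triangle distances are exact vectorized
  implementations (Möller–Trumbore; Ericson closest-point) chunked over
  rays/points; degenerate apex triangles are dropped before queries.
* Dense contour stacks are subsampled by a deterministic stride (≤ ~8000
  points/surface) before exact distance evaluation.
* Identical group means raise a degenerate-separation error; zero pooled
  variance in a mode comparison yields p = 1 with a warning; LOO folds that
  would empty a class are skipped with a warning and counted.
* Thresholds are compared inclusively (≥ 30/50 mmHg on the obstructive
  side); missing stress measurements exclude a subject from the Δstress
  comparison (no imputation).
* No multiplicity correction is applied to the per-mode t-tests by default
  (a Bonferroni flag exists): the tests are a descriptive screen, and the
  discriminant — not the screen — is the inferential object.
* HDF5 outputs are written with `track_times=False`; identical runs produce
  byte-identical files, which the manifest (config hash + per-file SHA-256)
  makes checkable.

## Problem sizes

The shipped study sizes — 60 subjects/group for the orchestrated study,
20 subjects for fitting-accuracy measurement, 200/group for
direction-recovery and Gaussian-calibration checks — were chosen so each
quantity's sampling error is small relative to the effect being
demonstrated while a complete run stays interactive on a laptop.

## Known limitations

* The generator's shape distribution is low-dimensional by construction;
  mode counts and variance fractions are not comparable to real cohorts.
* Rotational (circumferential) correspondence of fitted meshes comes from
  the acquisition frame, not from anatomical landmarks.
* The flow-continuity velocity model understates the velocity amplification
  of systolic anterior motion; severe (≥50 mmHg) gradients are rare under
  the default design, and the severe-threshold robustness analysis is
  accordingly run on a higher-velocity referral mix.
* Basal/apical slice truncation effects and right-ventricular anatomy are
  out of scope.
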