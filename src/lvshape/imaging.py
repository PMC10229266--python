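"""Voxelized segmentations and short-axis contour stacks.

Runs the contouring workflow in reverse: a surface mesh is rasterized into a
binary myocardium mask on a short-axis voxel grid (default 2 mm in-plane,
8 mm slice thickness, typical cine CMR), and per-slice endo/epi contours are
recovered from the mask boundaries by marching squares.  The mask is the
input the template-fitting stage consumes; the contours are the reference
against which fitting accuracy is scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .mesh import LVMesh

__all__ = [
    "BinaryMask",
    "SliceContours",
    "ContourStack",
    "ResolutionError",
    "voxelize",
    "extract_contours",
]

_MIN_CONTOUR_POINTS = 8


class ResolutionError(ValueError):
    """Raised when voxel spacing is too coarse to contour the myocardium."""


@dataclass
class BinaryMask:
    """Binary myocardium segmentation on a short-axis grid.

    ``data`` is indexed ``[ix, iy, islice]`` with slices ordered base->apex.
    ``affine`` maps voxel indices to world mm (homogeneous 4x4); the world
    frame is the anatomical frame of the meshes.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) along the three axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def slice_z(self, k: int) -> float:
        """World z of slice k's centre plane."""
        return float(self.voxel_to_world([[0.0, 0.0, float(k)]])[0, 2])

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img) -> "BinaryMask":
        return cls(data=np.asarray(img.dataobj) > 0, affine=np.asarray(img.affine))


@dataclass
class SliceContours:
    """Closed endo/epi polylines of one short-axis slice (world mm)."""

    z: float
    endo: list = field(default_factory=list)
    epi: list = field(default_factory=list)


@dataclass
class ContourStack:
    """Per-slice contour sets, ordered base->apex."""

    slices: list

    def points(self, surface: str) -> np.ndarray:
        """All contour points of one surface, stacked (N, 3)."""
        chunks = []
        for s in self.slices:
            for poly in getattr(s, surface):
                chunks.append(poly)
        if not chunks:
            return np.empty((0, 3))
        return np.vstack(chunks)

    def to_json(self) -> str:
        payload = {
            "format": "lvshape-contour-stack",
            "version": 1,
            "slices": [
                {
                    "z_mm": s.z,
                    "endo": [p.tolist() for p in s.endo],
                    "epi": [p.tolist() for p in s.epi],
                }
                for s in self.slices
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ContourStack":
        payload = json.loads(text)
        slices = [
            SliceContours(
                z=float(s["z_mm"]),
                endo=[np.asarray(p, dtype=float) for p in s["endo"]],
                epi=[np.asarray(p, dtype=float) for p in s["epi"]],
            )
            for s in payload["slices"]
        ]
        return cls(slices=slices)


# --------------------------------------------------------------------------
def voxelize(
    mesh: LVMesh, in_plane_mm: float = 2.0, slice_mm: float = 8.0
) -> tuple[BinaryMask, ContourStack]:
    """Rasterize a mesh into a binary mask and recover slice contours.

    A voxel belongs to the myocardium when its centre lies between the
    endocardial and epicardial surfaces.  The slice stack covers the full
    long-axis extent of the mesh (``n_slices = ceil(extent / slice_mm)``)
    starting at the base; in-plane the grid covers the mesh bounding box plus
    a two-voxel margin.  Containment is evaluated radially per meridian
    column, which is exact for the star-shaped cross-sections this package
    generates.
    """
    if not 0.0 < in_plane_mm <= 5.0:
        raise ValueError("in_plane_mm must lie in (0, 5]")
    if not 0.0 < slice_mm <= 12.0:
        raise ValueError("slice_mm must lie in (0, 12]")

    endo = mesh.endo_points
    epi = mesh.epi_points
    all_pts = np.concatenate([endo.reshape(-1, 3), epi.reshape(-1, 3)])
    z_top = float(all_pts[:, 2].max())
    z_bot = float(all_pts[:, 2].min())
    n_slices = int(math.ceil((z_top - z_bot) / slice_mm))

    margin = 2.0 * in_plane_mm
    x0 = float(all_pts[:, 0].min()) - margin
    y0 = float(all_pts[:, 1].min()) - margin
    nx = int(math.ceil((all_pts[:, 0].max() + margin - x0) / in_plane_mm))
    ny = int(math.ceil((all_pts[:, 1].max() + margin - y0) / in_plane_mm))

    affine = np.array(
        [
            [in_plane_mm, 0.0, 0.0, x0 + 0.5 * in_plane_mm],
            [0.0, in_plane_mm, 0.0, y0 + 0.5 * in_plane_mm],
            [0.0, 0.0, -slice_mm, z_top - 0.5 * slice_mm],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )

    xs = x0 + (np.arange(nx) + 0.5) * in_plane_mm
    ys = y0 + (np.arange(ny) + 0.5) * in_plane_mm
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    rho = np.hypot(xx, yy)
    phi = np.mod(np.arctan2(yy, xx), 2.0 * np.pi)

    theta = mesh.node_theta
    data = np.zeros((nx, ny, n_slices), dtype=bool)
    for k in range(n_slices):
        z = z_top - (k + 0.5) * slice_mm
        r_in = _cavity_radius_at(endo, z)  # per column, NaN above/below cavity
        r_out = _outer_radius_at(epi, z)
        if np.all(np.isnan(r_out)):
            continue
        r_in_v = _interp_angular(phi, theta, np.where(np.isnan(r_in), 0.0, r_in))
        r_out_v = _interp_angular(phi, theta, np.where(np.isnan(r_out), -1.0, r_out))
        data[:, :, k] = (rho <= r_out_v) & (rho >= r_in_v)

    # drop entirely empty slices at either end (ceil can overshoot the apex)
    occupied = np.flatnonzero(data.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ResolutionError("mesh rasterized to an empty mask")
    k0, k1 = int(occupied[0]), int(occupied[-1])
    data = data[:, :, k0 : k1 + 1]
    affine = affine.copy()
    affine[:3, 3] += affine[:3, 2] * k0

    mask = BinaryMask(data=data, affine=affine)
    contours = extract_contours(mask)
    return mask, contours


def _cavity_radius_at(endo: np.ndarray, z: float) -> np.ndarray:
    """Endocardial radius per meridian column at height z (NaN if absent).

    Endocardial node z decreases monotonically with u by construction, so a
    single linear interpolation along each column suffices.
    """
    n_long, n_circ, _ = endo.shape
    out = np.full(n_circ, np.nan)
    r = np.hypot(endo[..., 0], endo[..., 1])
    zc = endo[..., 2]
    for j in range(n_circ):
        zj = zc[:, j]
        if z > zj[0] or z < zj[-1]:
            continue
        out[j] = np.interp(z, zj[::-1], r[::-1, j])
    return out


def _outer_radius_at(epi: np.ndarray, z: float) -> np.ndarray:
    """Largest epicardial radius per column at height z (segment scan).

    The epicardial meridian can be locally non-monotonic in z near the apex,
    so every segment crossing the plane is considered and the outermost
    radius taken.
    """
    r = np.hypot(epi[..., 0], epi[..., 1])
    zc = epi[..., 2]
    z0, z1 = zc[:-1], zc[1:]
    r0, r1 = r[:-1], r[1:]
    lo = np.minimum(z0, z1)
    hi = np.maximum(z0, z1)
    crosses = (z >= lo) & (z <= hi)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(np.abs(z1 - z0) > 1e-12, (z - z0) / (z1 - z0), 0.0)
    r_at = r0 + t * (r1 - r0)
    r_at = np.where(crosses, r_at, -np.inf)
    best = r_at.max(axis=0)
    return np.where(np.isfinite(best), best, np.nan)


def _interp_angular(
    phi: np.ndarray, theta: np.ndarray, values: np.ndarray
) -> np.ndarray:
    """Periodic linear interpolation of per-column values at query angles."""
    period = 2.0 * np.pi
    theta_ext = np.concatenate([theta, [theta[0] + period]])
    values_ext = np.concatenate([values, [values[0]]])
    return np.interp(np.mod(phi - theta[0], period) + theta[0], theta_ext, values_ext)


# --------------------------------------------------------------------------
def extract_contours(mask: BinaryMask) -> ContourStack:
    """Marching-squares endo/epi contours from a binary mask, in world mm.

    Outer boundaries (not enclosed by another contour) become epicardial
    contours, enclosed boundaries endocardial ones.  Contours shorter than 8
    points are discarded as resolution artefacts; if an interior slice loses
    every boundary, or no slice yields contours at all, the spacing is deemed
    too coarse and :class:`ResolutionError` is raised.
    """
    from matplotlib.path import Path

    slices = []
    populated = []
    for k in range(mask.n_slices):
        img = mask.data[:, :, k].astype(float)
        found = measure.find_contours(img, 0.5)
        found = [c for c in found if len(c) >= _MIN_CONTOUR_POINTS]
        paths = [Path(c) for c in found]
        outer_flags = []
        for i, c in enumerate(found):
            rep = c[0]
            inside_other = any(
                j != i and paths[j].contains_point(rep) for j in range(len(found))
            )
            outer_flags.append(not inside_other)
        z = mask.slice_z(k)
        sc = SliceContours(z=z)
        for c, is_outer in zip(found, outer_flags):
            ijk = np.column_stack([c, np.full(len(c), float(k))])
            world = mask.voxel_to_world(ijk)
            (sc.epi if is_outer else sc.endo).append(world)
        slices.append(sc)
        populated.append(bool(sc.epi))
    if not any(populated):
        raise ResolutionError("no usable contours in any slice")
    first = populated.index(True)
    last = len(populated) - 1 - populated[::-1].index(True)
    if not all(populated[first : last + 1]):
        raise ResolutionError(
            "interior slice without a closed epicardial contour; voxel "
            "spacing too coarse for this geometry"
        )
    return ContourStack(slices=slices)
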