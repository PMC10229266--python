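"""Corresponded left-ventricular surface meshes.

The whole pipeline operates on a single mesh topology: an endocardial and an
epicardial surface, each sampled on a fixed (longitudinal x circumferential)
grid.  Rows index the longitudinal fraction ``u`` (0 = base, 1 = apex), columns
the circumferential angle ``theta``.  Because every subject shares the grid,
node ``(i, j)`` of any two meshes refers to the same anatomical location and
shapes can be compared coordinate-wise (point-distribution-model
correspondence by construction).

Anatomical frame convention used everywhere in this package:

* the LV long axis is ``z`` with the base at ``z = 0`` and the apex at
  negative ``z``;
* ``theta = 0`` points at the centre of the anteroseptal outflow-tract (LVOT)
  sector and increases counter-clockwise when viewed from the apex (the
  bull's-eye convention);
* the septum occupies a fixed 120 degree sector centred on ``theta = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LVMesh",
    "TopologyError",
    "LVOT_SECTOR_HALF_ANGLE_RAD",
    "LVOT_SECTOR_MAX_U",
    "wrap_angle",
    "lvot_sector_mask",
    "lvot_sector_radius",
    "lvot_sector_area",
]

#: Half-angle of the basal anteroseptal LVOT sector (30 degrees either side of
#: theta = 0) and its longitudinal extent (basal third of the long axis).
LVOT_SECTOR_HALF_ANGLE_RAD = np.pi / 6.0
LVOT_SECTOR_MAX_U = 1.0 / 3.0


class TopologyError(ValueError):
    """Raised when meshes with incompatible grid topologies are combined."""


def wrap_angle(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angle), 2.0 * np.pi)


@dataclass
class LVMesh:
    """Endo+epi surface point grids with shared, fixed topology.

    Parameters
    ----------
    endo_points, epi_points:
        Arrays of shape ``(n_long, n_circ, 3)`` in mm.  Row ``i`` holds the
        ring of nodes at longitudinal fraction ``node_u[i]``; column ``j``
        holds the meridian at angle ``node_theta[j]``.  The last row (u = 1)
        collapses to the apex point on the endocardium.
    node_theta:
        Circumferential angle per column, radians, length ``n_circ``.
    node_u:
        Longitudinal fraction per row in [0, 1], strictly increasing
        base -> apex, length ``n_long``.
    topology_id:
        Identifier guaranteeing shared connectivity between meshes.
    """

    endo_points: np.ndarray
    epi_points: np.ndarray
    node_theta: np.ndarray
    node_u: np.ndarray
    topology_id: str = field(default="")

    def __post_init__(self) -> None:
        self.endo_points = np.asarray(self.endo_points, dtype=float)
        self.epi_points = np.asarray(self.epi_points, dtype=float)
        self.node_theta = np.asarray(self.node_theta, dtype=float)
        self.node_u = np.asarray(self.node_u, dtype=float)
        if self.endo_points.shape != self.epi_points.shape:
            raise TopologyError("endo and epi grids must be congruent")
        if self.endo_points.ndim != 3 or self.endo_points.shape[2] != 3:
            raise TopologyError("point grids must have shape (n_long, n_circ, 3)")
        n_long, n_circ, _ = self.endo_points.shape
        if self.node_theta.shape != (n_circ,) or self.node_u.shape != (n_long,):
            raise TopologyError("node_theta/node_u inconsistent with grids")
        if np.any(np.diff(self.node_u) <= 0):
            raise ValueError("node_u must be strictly increasing base->apex")
        if not self.topology_id:
            self.topology_id = f"lvgrid-{n_circ}x{n_long}"

    # ------------------------------------------------------------------ shape
    @property
    def n_long(self) -> int:
        return self.endo_points.shape[0]

    @property
    def n_circ(self) -> int:
        return self.endo_points.shape[1]

    @property
    def n_nodes(self) -> int:
        """Total number of nodes over both surfaces."""
        return 2 * self.n_long * self.n_circ

    def points(self, surface: str) -> np.ndarray:
        if surface == "endo":
            return self.endo_points
        if surface == "epi":
            return self.epi_points
        raise ValueError(f"unknown surface {surface!r}")

    # --------------------------------------------------------- vector <-> mesh
    def as_vector(self) -> np.ndarray:
        """Flatten to a shape vector (endo rows first, then epi), length 3M."""
        return np.concatenate(
            [self.endo_points.reshape(-1), self.epi_points.reshape(-1)]
        )

    def as_points(self) -> np.ndarray:
        """All nodes as an (M, 3) array (endo then epi)."""
        return np.concatenate(
            [self.endo_points.reshape(-1, 3), self.epi_points.reshape(-1, 3)]
        )

    def with_vector(self, vector: np.ndarray) -> "LVMesh":
        """Return a copy of this mesh with coordinates taken from ``vector``."""
        vector = np.asarray(vector, dtype=float)
        half = self.n_long * self.n_circ * 3
        if vector.size != 2 * half:
            raise TopologyError(
                f"shape vector of length {vector.size} does not match "
                f"topology {self.topology_id}"
            )
        shape = (self.n_long, self.n_circ, 3)
        return LVMesh(
            endo_points=vector[:half].reshape(shape),
            epi_points=vector[half:].reshape(shape),
            node_theta=self.node_theta.copy(),
            node_u=self.node_u.copy(),
            topology_id=self.topology_id,
        )

    def with_points(self, points: np.ndarray) -> "LVMesh":
        return self.with_vector(np.asarray(points, dtype=float).reshape(-1))

    # ------------------------------------------------------------ triangulation
    def surface_triangles(self, surface: str) -> np.ndarray:
        """Triangles of one surface as an (n_tri, 3, 3) coordinate array.

        The quad grid is split into two triangles per cell; degenerate
        triangles produced by the collapsed apex row are dropped.
        """
        pts = self.points(surface)
        faces = grid_faces(self.n_long, self.n_circ)
        flat = pts.reshape(-1, 3)
        tri = flat[faces]
        # drop zero-area triangles (apex row duplicates)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cross, axis=1)
        return tri[area2 > 1e-12]

    def to_trimesh(self, surface: str, cap_base: bool = False):
        """Export one surface as a :class:`trimesh.Trimesh`.

        With ``cap_base=True`` the open basal ring is closed with a fan so the
        result is watertight (used for volume computations).
        """
        import trimesh

        pts = self.points(surface).reshape(-1, 3)
        faces = grid_faces(self.n_long, self.n_circ)
        if cap_base:
            centre = pts[: self.n_circ].mean(axis=0)
            ci = len(pts)
            pts = np.vstack([pts, centre])
            ring = np.arange(self.n_circ)
            cap = np.stack(
                [np.full(self.n_circ, ci), np.roll(ring, -1), ring], axis=1
            )
            faces = np.vstack([faces, cap])
        mesh = trimesh.Trimesh(vertices=pts, faces=faces, process=False)
        return mesh

    # ---------------------------------------------------------------- normals
    def node_normals(self, surface: str) -> np.ndarray:
        """Outward unit normals at every grid node, shape (n_long, n_circ, 3).

        "Outward" means pointing from the cavity towards the chest wall on
        both surfaces (endo -> epi direction on the endocardium).  Normals are
        estimated from central finite differences on the grid and oriented
        away from the mesh centroid; the degenerate apex row falls back to the
        apex-minus-centroid direction.
        """
        pts = self.points(surface)
        n_long, n_circ, _ = pts.shape
        # circumferential tangent: periodic central difference
        t_theta = np.roll(pts, -1, axis=1) - np.roll(pts, 1, axis=1)
        # longitudinal tangent: one-sided at the ends
        t_u = np.empty_like(pts)
        t_u[1:-1] = pts[2:] - pts[:-2]
        t_u[0] = pts[1] - pts[0]
        t_u[-1] = pts[-1] - pts[-2]
        normals = np.cross(t_theta, t_u)
        norms = np.linalg.norm(normals, axis=2, keepdims=True)
        centroid = pts.reshape(-1, 3).mean(axis=0)
        radial = pts - centroid
        bad = norms[..., 0] < 1e-9
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = normals / norms
        # orient away from the centroid (star-shaped assumption)
        flip = np.sum(normals * radial, axis=2) < 0
        normals[flip] *= -1.0
        if np.any(bad):
            fallback = radial[bad]
            fallback /= np.linalg.norm(fallback, axis=1, keepdims=True)
            normals[bad] = fallback
        return normals


def grid_faces(n_long: int, n_circ: int) -> np.ndarray:
    """Triangle index pairs for one (n_long x n_circ) periodic grid."""
    i = np.arange(n_long - 1)[:, None]
    j = np.arange(n_circ)[None, :]
    jp = (j + 1) % n_circ
    a = i * n_circ + j
    b = i * n_circ + jp
    c = (i + 1) * n_circ + j
    d = (i + 1) * n_circ + jp
    t1 = np.stack(np.broadcast_arrays(a, b, d), axis=-1).reshape(-1, 3)
    t2 = np.stack(np.broadcast_arrays(a, d, c), axis=-1).reshape(-1, 3)
    return np.vstack([t1, t2])


# --------------------------------------------------------------- LVOT sector
def lvot_sector_mask(mesh: LVMesh) -> np.ndarray:
    """Boolean (n_long, n_circ) mask of nodes in the basal anteroseptal
    LVOT sector (u < 1/3, |theta| <= 30 degrees)."""
    in_u = mesh.node_u < LVOT_SECTOR_MAX_U
    in_theta = np.abs(wrap_angle(mesh.node_theta)) <= LVOT_SECTOR_HALF_ANGLE_RAD
    return np.outer(in_u, in_theta)


def lvot_sector_radius(mesh: LVMesh) -> float:
    """Mean endocardial radius (mm, distance to the long axis) over the
    basal anteroseptal LVOT sector."""
    sel = lvot_sector_mask(mesh)
    if not np.any(sel):
        raise ValueError("mesh grid has no nodes inside the LVOT sector")
    pts = mesh.endo_points[sel]
    return float(np.mean(np.hypot(pts[:, 0], pts[:, 1])))


def lvot_sector_area(mesh: LVMesh) -> float:
    """Effective cross-sectional area (mm^2) of the LVOT sector.

    Modelled as a 60 degree circular sector of the sector-mean endocardial
    radius: ``A = (pi/6) * r_mean^2``.  Inward remodelling of the basal
    anteroseptal wall reduces ``r_mean`` and therefore the effective area.
    """
    r = lvot_sector_radius(mesh)
    return float(np.pi / 6.0 * r * r)
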