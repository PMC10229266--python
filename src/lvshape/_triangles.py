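"""Vectorized triangle queries (ray casting and closest-point distances).

Self-contained numpy implementations used for wall-thickness ray casting and
surface-to-contour distances.  Both routines broadcast rays/points against all
triangles in chunks, which is fast enough for the grid sizes this package
works with (a few thousand nodes against a few thousand triangles).
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def ray_surface_distance(
    origins: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    t_min: float = 1e-9,
    chunk: int = 256,
) -> np.ndarray:
    """Distance along each ray to its first triangle intersection.

    Möller–Trumbore intersection of ``origins[i] + t * directions[i]`` with a
    triangle soup of shape ``(n_tri, 3, 3)``.  Returns the smallest ``t`` above
    ``t_min`` per ray, or NaN where the ray misses the surface.  Directions
    need not be normalized; ``t`` is in units of the direction length.
    """
    origins = np.asarray(origins, dtype=float)
    directions = np.asarray(directions, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0

    out = np.full(len(origins), np.nan)
    for start in range(0, len(origins), chunk):
        o = origins[start : start + chunk, None, :]
        d = directions[start : start + chunk, None, :]
        pvec = np.cross(d, e2[None, :, :])
        det = np.einsum("rtk,tk->rt", pvec, e1)
        valid = np.abs(det) > _EPS
        inv_det = np.where(valid, 1.0 / np.where(valid, det, 1.0), 0.0)
        tvec = o - v0[None, :, :]
        u = np.einsum("rtk,rtk->rt", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rtk,rtk->rt", qvec, d) * inv_det
        t = np.einsum("rtk,tk->rt", qvec, e2) * inv_det
        hit = (
            valid
            & (u >= -1e-9)
            & (v >= -1e-9)
            & (u + v <= 1.0 + 1e-9)
            & (t > t_min)
        )
        t = np.where(hit, t, np.inf)
        best = t.min(axis=1)
        out[start : start + chunk] = np.where(np.isfinite(best), best, np.nan)
    return out


def point_surface_distance(
    points: np.ndarray, triangles: np.ndarray, chunk: int = 128
) -> np.ndarray:
    """Exact unsigned distance from each point to a triangle soup.

    Classic closest-point-on-triangle region test (Ericson, *Real-Time
    Collision Detection*), vectorized over (point, triangle) pairs.
    """
    points = np.asarray(points, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    a = triangles[:, 0][None]
    ab = (triangles[:, 1] - triangles[:, 0])[None]
    ac = (triangles[:, 2] - triangles[:, 0])[None]

    out = np.empty(len(points))
    for start in range(0, len(points), chunk):
        p = points[start : start + chunk, None, :]
        ap = p - a
        d1 = np.einsum("ptk,ptk->pt", ab, ap)
        d2 = np.einsum("ptk,ptk->pt", ac, ap)
        bp = p - (a + ab)
        d3 = np.einsum("ptk,ptk->pt", ab, bp)
        d4 = np.einsum("ptk,ptk->pt", ac, bp)
        cp = p - (a + ac)
        d5 = np.einsum("ptk,ptk->pt", ab, cp)
        d6 = np.einsum("ptk,ptk->pt", ac, cp)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2
        denom_v = np.where(np.abs(d1 - d3) > _EPS, d1 - d3, _EPS)
        denom_w = np.where(np.abs(d2 - d6) > _EPS, d2 - d6, _EPS)
        denom_vw = np.where(
            np.abs((d4 - d3) + (d5 - d6)) > _EPS, (d4 - d3) + (d5 - d6), _EPS
        )
        denom_bary = np.where(np.abs(va + vb + vc) > _EPS, va + vb + vc, _EPS)

        # region tests, applied in priority order via np.select
        v_edge_ab = np.clip(d1 / denom_v, 0.0, 1.0)
        w_edge_ac = np.clip(d2 / denom_w, 0.0, 1.0)
        w_edge_bc = np.clip((d4 - d3) / denom_vw, 0.0, 1.0)
        v_face = vb / denom_bary
        w_face = vc / denom_bary

        in_a = (d1 <= 0) & (d2 <= 0)
        in_b = (d3 >= 0) & (d4 <= d3)
        in_c = (d6 >= 0) & (d5 <= d6)
        on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        on_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

        v = np.select(
            [in_a, in_b, in_c, on_ab, on_ac, on_bc],
            [0.0, 1.0, 0.0, v_edge_ab, 0.0, 1.0 - w_edge_bc],
            default=np.clip(v_face, 0.0, 1.0),
        )
        w = np.select(
            [in_a, in_b, in_c, on_ab, on_ac, on_bc],
            [0.0, 0.0, 1.0, 0.0, w_edge_ac, w_edge_bc],
            default=np.clip(w_face, 0.0, 1.0),
        )
        closest = a + v[..., None] * ab + w[..., None] * ac
        dist = np.linalg.norm(p - closest, axis=2)
        out[start : start + chunk] = dist.min(axis=1)
    return out
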