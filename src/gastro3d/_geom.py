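"""Vectorized geometric kernels: point-to-mesh distance and ray-mesh casting.

Both operate on raw (vertices, faces) arrays and use a kd-tree on triangle
centroids only to prune candidates; the distance itself is the exact
point-to-triangle Euclidean distance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["point_triangle_distance", "points_to_mesh_distance", "ray_mesh_first_hit"]


def point_triangle_distance(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact unsigned distance from points[i] to triangles[i] (paired).

    ``points``: (N, 3); ``triangles``: (N, 3, 3).  Implementation follows the
    standard region classification of the closest point on a triangle
    (Ericson, Real-Time Collision Detection, ch. 5).
    """
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    denom = np.where(denom == 0, 1.0, denom)
    v = (d1 / denom)[:, None]
    closest[m] = a[m] + v[m] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    denom = np.where(denom == 0, 1.0, denom)
    w = (d2 / denom)[:, None]
    closest[m] = a[m] + w[m] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom == 0, 1.0, denom)
    w = ((d4 - d3) / denom)[:, None]
    closest[m] = b[m] + w[m] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    closest[m] = a[m] + v[m] * ab[m] + w[m] * ac[m]

    return np.linalg.norm(p - closest, axis=1)


def points_to_mesh_distance(
    points: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    n_candidates: int = 32,
) -> np.ndarray:
    """Unsigned distance from each point to the nearest mesh triangle.

    Candidate triangles are the ``n_candidates`` with nearest centroid
    (kd-tree); the reported distance is the exact minimum over candidates.
    A candidate count of a few dozen is ample for the smooth, roughly
    uniformly triangulated meshes this package produces.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValueError("mesh has no faces")
    tris = vertices[faces]  # (F, 3, 3)
    centroids = tris.mean(axis=1)
    k = min(n_candidates, len(faces))
    _, cand = cKDTree(centroids).query(points, k=k)
    cand = np.atleast_2d(cand)
    if cand.ndim == 1:
        cand = cand[:, None]
    n = len(points)
    best = np.full(n, np.inf)
    # chunk over candidate columns to bound memory
    for j in range(cand.shape[1]):
        d = point_triangle_distance(points, tris[cand[:, j]])
        best = np.minimum(best, d)
    return best


def ray_mesh_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    vertices: np.ndarray,
    faces: np.ndarray,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First intersection of each ray with a triangle mesh (Möller–Trumbore).

    Returns ``(hit_mask (R,), locations (R, 3), face_index (R,))``; rows of
    non-hitting rays hold NaN locations and face index -1.  Rays starting
    inside a closed mesh are valid (an endoscope films from inside the organ).
    Fully vectorized over rays x triangles, chunked to bound memory.
    """
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    tris = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=np.int64)]
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0

    n_rays = len(origins)
    hit = np.zeros(n_rays, dtype=bool)
    t_best = np.full(n_rays, np.inf)
    face_best = np.full(n_rays, -1, dtype=np.int64)

    chunk = max(1, int(4e6 // max(len(tris), 1)))
    for start in range(0, n_rays, chunk):
        o = origins[start : start + chunk]  # (r, 3)
        d = directions[start : start + chunk]
        # (r, F, 3) broadcasting
        pvec = np.cross(d[:, None, :], e2[None, :, :])
        det = np.einsum("fj,rfj->rf", e1, pvec)
        ok = np.abs(det) > eps
        inv_det = np.where(ok, 1.0 / np.where(det == 0, 1.0, det), 0.0)
        tvec = o[:, None, :] - v0[None, :, :]
        u = np.einsum("rfj,rfj->rf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rj,rfj->rf", d, qvec) if False else np.einsum("rfj,rj->rf", qvec, d)
        v = v * inv_det
        t = np.einsum("fj,rfj->rf", e2, qvec) * inv_det
        ok &= (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        t = np.where(ok, t, np.inf)
        idx = np.argmin(t, axis=1)
        tmin = t[np.arange(len(o)), idx]
        got = np.isfinite(tmin)
        sl = slice(start, start + len(o))
        hit[sl] = got
        t_best[sl] = tmin
        face_best[sl] = np.where(got, idx, -1)

    locations = np.full((n_rays, 3), np.nan)
    locations[hit] = origins[hit] + t_best[hit, None] * directions[hit]
    return hit, locations, face_best
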