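"""Normal estimation/orientation and surface meshing of cleaned clouds.

Per-point normals come from local PCA (the eigenvector of the smallest
covariance eigenvalue over the k nearest neighbours, k = 100 by default).
Because PCA leaves the sign free, normals are then oriented using the
registered endoscope poses: the camera films the organ wall from inside the
cavity, so a point's normal must face the cameras that observed it.  A light
neighbourhood smoothing regularises the oriented field before meshing.

Meshing is implicit-surface reconstruction from the oriented points: a signed
distance field f(x) = weighted mean over nearby points p_j of n_j . (x - p_j)
is sampled on a uniform grid of ``2**depth`` cells per axis and contoured at
zero with marching cubes.  ``depth`` therefore plays the familiar
octree-depth role: low depth gives a very smooth, low-resolution surface,
higher depth resolves finer anatomy (rugae-scale detail at depth 7-8 for
typical scenes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import SparseReconstruction, TriangleMesh, INVALID_POINT3D
from ._geom import points_to_mesh_distance

__all__ = [
    "NormalField",
    "CameraScore",
    "estimate_normals",
    "orient_normals",
    "orient_toward_point",
    "smooth_normals",
    "reconstruct_surface",
    "score_cameras_for_face",
    "transfer_vertex_colors",
    "SENTINEL_GRAY",
]

#: color given to vertices visible from no registered camera
SENTINEL_GRAY = np.array([128, 128, 128], dtype=np.uint8)


@dataclass
class NormalField:
    """Unit normals index-aligned to a point cloud, with provenance flags."""

    normals: np.ndarray
    oriented: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        lens = np.linalg.norm(self.normals, axis=1)
        if len(lens) and np.any(np.abs(lens - 1.0) > 1e-9):
            raise ValueError("normals must be unit length (within 1e-9)")


@dataclass(frozen=True)
class CameraScore:
    """Suitability of one registered frame for texturing a mesh face."""

    frame_id: int
    angle_cos: float  # cosine between surface normal and direction to camera
    distance: float  # scene units
    score: float


def _as_points(cloud) -> np.ndarray:
    pts = getattr(cloud, "points", cloud)
    return np.asarray(pts, dtype=float).reshape(-1, 3)


def estimate_normals(cloud, k: int = 100) -> NormalField:
    """Per-point PCA normals over the k nearest neighbours (sign arbitrary).

    The normal is the eigenvector of the smallest eigenvalue of the local
    covariance; ``k`` is clamped to N-1.  Batched eigendecomposition keeps
    this fast for clouds of tens of thousands of points.
    """
    pts = _as_points(cloud)
    n = len(pts)
    if n < 3:
        raise ValueError("normal estimation requires at least 3 points")
    k = min(k, n - 1)
    _, idx = cKDTree(pts).query(pts, k=k + 1)  # includes self
    covs = np.empty((n, 3, 3))
    chunk = max(1, int(5e6) // (k + 1))
    for s in range(0, n, chunk):
        nb = pts[idx[s : s + chunk]]  # (c, k+1, 3)
        nb = nb - nb.mean(axis=1, keepdims=True)
        covs[s : s + chunk] = np.einsum("cki,ckj->cij", nb, nb) / (k + 1)
    _, vecs = np.linalg.eigh(covs)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    return NormalField(normals / lens, oriented=False, smoothed=False)


def orient_toward_point(points: np.ndarray, normals: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Flip normals so each points toward ``target`` (dot >= 0 kept as is)."""
    points = _as_points(points)
    normals = np.asarray(normals, dtype=float).reshape(-1, 3)
    to_target = np.asarray(target, dtype=float).reshape(3) - points
    flip = np.einsum("ij,ij->i", normals, to_target) < 0
    out = normals.copy()
    out[flip] = -out[flip]
    return out


def orient_normals(cloud, normals: NormalField | np.ndarray, recon: SparseReconstruction) -> NormalField:
    """Orient normals toward the cameras that observed each point.

    For a tracked point the normal is flipped so it points toward the mean
    centre of its observing cameras (``dot(n, c_bar - p) >= 0``; an exactly
    orthogonal normal is kept unflipped).  Points without a track — or clouds
    not drawn from the reconstruction — use the globally nearest camera
    centre.  This guarantees normals face into the cavity where the endoscope
    travels rather than outward.
    """
    pts = _as_points(cloud)
    nrm = normals.normals if isinstance(normals, NormalField) else np.asarray(normals, dtype=float)
    nrm = nrm.reshape(-1, 3).copy()
    if len(pts) != len(nrm):
        raise ValueError("points and normals must be index-aligned")
    if not recon.frames:
        raise ValueError("reconstruction has no registered frames to orient against")

    centers = {fid: fr.camera_center for fid, fr in recon.frames.items()}
    center_arr = np.array(list(centers.values()))
    center_tree = cKDTree(center_arr)

    ids = getattr(cloud, "ids", None)
    targets = np.empty_like(pts)
    for i in range(len(pts)):
        track = None
        if ids is not None:
            pt = recon.points.get(int(ids[i]))
            if pt is not None and pt.track:
                track = pt.track
        if track:
            targets[i] = np.mean([centers[fid] for fid, _ in track if fid in centers], axis=0)
        else:
            _, j = center_tree.query(pts[i])
            targets[i] = center_arr[j]

    flip = np.einsum("ij,ij->i", nrm, targets - pts) < 0
    nrm[flip] = -nrm[flip]
    return NormalField(nrm, oriented=True, smoothed=False)


def smooth_normals(cloud, normals: NormalField | np.ndarray, k_smooth: int = 10) -> NormalField:
    """Replace each normal by the renormalised mean over its k-NN normals.

    The neighbourhood includes the point itself, so ``k_smooth = 1`` is the
    identity; a uniform field is a fixed point.  A single flipped normal among
    aligned neighbours is restored to the majority direction.
    """
    pts = _as_points(cloud)
    nrm = normals.normals if isinstance(normals, NormalField) else np.asarray(normals, dtype=float)
    nrm = nrm.reshape(-1, 3)
    k = min(k_smooth, len(pts))
    if k <= 1:
        return NormalField(nrm.copy(), oriented=True, smoothed=True)
    _, idx = cKDTree(pts).query(pts, k=k)
    idx = np.atleast_2d(idx)
    mean = nrm[idx].mean(axis=1)
    lens = np.linalg.norm(mean, axis=1, keepdims=True)
    degenerate = lens[:, 0] < 1e-12
    mean[degenerate] = nrm[degenerate]  # cancelled mean: keep original
    lens[degenerate] = 1.0
    return NormalField(mean / np.where(lens == 0, 1.0, lens), oriented=True, smoothed=True)


def reconstruct_surface(
    cloud,
    normals: NormalField | np.ndarray,
    depth: int = 8,
    k_field: int = 8,
    padding: float = 0.08,
) -> TriangleMesh:
    """Mesh an oriented point cloud by contouring a signed distance field.

    The field at a grid node is the inverse-distance-weighted mean of the
    point-plane signed distances ``n_j . (x - p_j)`` over the ``k_field``
    nearest cloud points; marching cubes extracts the zero level set on a
    ``2**depth``-per-axis grid over the padded bounding box.  With
    consistently oriented normals the result is a closed (or near-closed)
    surface whose resolution is set by ``depth``.
    """
    from skimage.measure import marching_cubes

    pts = _as_points(cloud)
    nrm = normals.normals if isinstance(normals, NormalField) else np.asarray(normals, dtype=float)
    nrm = nrm.reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("cannot reconstruct a surface from an empty cloud")
    if len(pts) != len(nrm):
        raise ValueError("points and normals must be index-aligned")
    if depth < 2:
        raise ValueError("depth must be >= 2")

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    if np.all(span == 0):
        raise ValueError("degenerate input: all points coincide")
    pad = padding * np.linalg.norm(span)
    lo = lo - pad
    hi = hi + pad

    res = 2**depth
    axes = [np.linspace(lo[i], hi[i], res) for i in range(3)]
    spacing = [(hi[i] - lo[i]) / (res - 1) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    tree = cKDTree(pts)
    k = min(k_field, len(pts))
    field = np.empty(len(grid))
    chunk = max(1, int(4e6) // k)
    for s in range(0, len(grid), chunk):
        g = grid[s : s + chunk]
        d, idx = tree.query(g, k=k)
        d = np.atleast_2d(d)
        idx = np.atleast_2d(idx)
        signed = np.einsum("ckj,ckj->ck", nrm[idx], g[:, None, :] - pts[idx])
        w = 1.0 / (d + 1e-12)
        field[s : s + chunk] = (signed * w).sum(axis=1) / w.sum(axis=1)
    field = field.reshape(res, res, res)

    if field.min() >= 0 or field.max() <= 0:
        raise ValueError("signed field has no zero crossing; check normal orientation")
    verts, faces, _, _ = marching_cubes(field, level=0.0, spacing=spacing)
    verts = verts + lo
    # drop degenerate faces marching cubes occasionally emits on flat cells
    a, b, c = faces.T
    faces = faces[(a != b) & (b != c) & (a != c)]
    return TriangleMesh(verts, faces)


def _visible_mask(point: np.ndarray, recon: SparseReconstruction, frame_ids: list[int]) -> dict[int, np.ndarray]:
    """Pixel projection of one point in each frame; NaN if behind/outside."""
    out = {}
    for fid in frame_ids:
        fr = recon.frames[fid]
        cam = recon.cameras[fr.camera_id]
        uv = cam.project(fr.world_to_camera(point))[0]
        if np.any(np.isnan(uv)) or not (0 <= uv[0] < cam.width and 0 <= uv[1] < cam.height):
            out[fid] = None
        else:
            out[fid] = uv
    return out


def score_cameras_for_face(
    face_index: int, mesh: TriangleMesh, recon: SparseReconstruction
) -> list[CameraScore]:
    """Rank registered frames as texture sources for one face.

    A frame is a candidate when the face centroid lies in front of its camera
    and projects inside the image, and the camera is on the normal side of the
    face (``angle_cos > 0``).  Candidates are ranked by
    ``score = angle_cos / (1 + distance / r_mesh)`` descending — dimensionless
    and monotone in both "closest" and "most orthogonal".  Self-occlusion is
    not tested: a single cavity seen from inside has limited self-occlusion
    (see module docs).
    """
    centroid = mesh.face_centroids()[face_index]
    normal = mesh.face_normals()[face_index]
    r_mesh = mesh.bbox_diagonal or 1.0
    proj = _visible_mask(centroid, recon, sorted(recon.frames))
    scores = []
    for fid in sorted(recon.frames):
        if proj[fid] is None:
            continue
        c = recon.frames[fid].camera_center
        to_cam = c - centroid
        dist = float(np.linalg.norm(to_cam))
        if dist == 0:
            continue
        cos = float(normal @ (to_cam / dist))
        if cos <= 0:  # camera behind the face
            continue
        scores.append(CameraScore(fid, cos, dist, cos / (1.0 + dist / r_mesh)))
    scores.sort(key=lambda s: (-s.score, s.frame_id))
    return scores


def transfer_vertex_colors(
    mesh: TriangleMesh,
    recon: SparseReconstruction,
    frames,
) -> TriangleMesh:
    """Color mesh vertices by sampling each vertex's best-ranked camera image.

    ``frames`` is an RGB FrameSequence whose ``indices`` hold the registered
    frame ids.  Each vertex uses the same camera score as
    :func:`score_cameras_for_face` (with the vertex normal standing in for
    the face normal, oriented toward the cameras) and nearest-pixel sampling;
    vertices visible from no camera receive a sentinel gray.
    """
    if frames.channel != "RGB":
        raise ValueError("color transfer requires an RGB frame sequence")
    frame_by_id = {int(i): f for i, f in zip(frames.indices, frames.frames)}
    missing = [fid for fid in recon.frames if fid not in frame_by_id]
    if missing:
        raise FileNotFoundError(f"no image supplied for registered frames {missing}")

    verts = mesh.vertices
    vnorm = (
        mesh.vertex_normals
        if mesh.vertex_normals is not None
        else mesh.compute_vertex_normals()
    )
    r_mesh = mesh.bbox_diagonal or 1.0
    fids = sorted(recon.frames)
    centers = np.array([recon.frames[f].camera_center for f in fids])
    # normals must face the cameras; flip any pointing away from their mean
    vnorm = orient_toward_point(verts, vnorm, centers.mean(axis=0))

    n = len(verts)
    best_score = np.full(n, -np.inf)
    best_uv = np.full((n, 2), np.nan)
    best_fid = np.full(n, -1, dtype=np.int64)
    for fi, fid in enumerate(fids):
        fr = recon.frames[fid]
        cam = recon.cameras[fr.camera_id]
        uv = cam.project(fr.world_to_camera(verts))
        inside = (
            ~np.isnan(uv[:, 0])
            & (uv[:, 0] >= 0) & (uv[:, 0] < cam.width)
            & (uv[:, 1] >= 0) & (uv[:, 1] < cam.height)
        )
        to_cam = centers[fi] - verts
        dist = np.linalg.norm(to_cam, axis=1)
        dist_safe = np.where(dist == 0, 1.0, dist)
        cos = np.einsum("ij,ij->i", vnorm, to_cam / dist_safe[:, None])
        score = cos / (1.0 + dist / r_mesh)
        ok = inside & (cos > 0) & (score > best_score)
        best_score[ok] = score[ok]
        best_uv[ok] = uv[ok]
        best_fid[ok] = fid

    colors = np.tile(SENTINEL_GRAY, (n, 1))
    for fid in fids:
        sel = best_fid == fid
        if not sel.any():
            continue
        img = frame_by_id[fid]
        u = np.clip(best_uv[sel, 0].astype(int), 0, img.shape[1] - 1)
        v = np.clip(best_uv[sel, 1].astype(int), 0, img.shape[0] - 1)
        colors[sel] = img[v, u][:, :3]

    return TriangleMesh(
        verts, mesh.faces, vertex_normals=mesh.vertex_normals, vertex_colors=colors
    )
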