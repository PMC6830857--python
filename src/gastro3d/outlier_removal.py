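"""Four-stage point-cloud cleaning for sparse endoscopic reconstructions.

Sparse clouds triangulated from endoscope video carry two outlier families:
isolated points scattered far from the organ surface (spurious matches) and
near-surface points displaced by triangulation error.  The cleaning cascade
operates purely on scale-free statistics of the cloud itself:

1. **Isolated-point filter** — remove every point whose nearest-neighbour
   distance exceeds ``A * r``, where ``r`` is the bounding-box diagonal of the
   input cloud; recompute ``r`` on the survivors.
2. **Neighbourhood census** — each survivor gathers neighbours within radius
   ``r`` (capped at the ``neighbor_cap`` nearest); a point with fewer than
   ``M`` neighbours is removed (too sparse to support a plane fit).
3. **Local RANSAC plane filter** — fit a plane to each point's local set by
   random triples, record the centre point's distance ``D`` to its own best
   plane, and remove points with ``D`` above the global average of all
   recorded ``D`` (strictly; a zero-variance planar cloud loses nothing).
4. **Smooth-mesh filter** — reconstruct a deliberately low-resolution surface
   from the survivors, compute every point's unsigned distance to it, and
   remove points farther than ``B`` standard deviations of that distance
   distribution.

Published operating values: ``A = 0.05``, ``M = 80``, ``B = 5`` with a
100-nearest-neighbour cap.

Note that stage 3's above-average rule is intentionally aggressive: on a
smooth noisy cloud the distance statistic is continuously distributed, so a
substantial upper tail of perfectly good points is sacrificed along with the
outliers.  The rule buys a final cloud essentially free of near-surface
outliers at the price of density, which the downstream implicit meshing
tolerates well.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CleaningConfig",
    "PointCloudStage",
    "Plane",
    "CleaningReport",
    "OUTLIER_MARK",
    "bbox_diagonal",
    "remove_isolated",
    "gather_neighborhood",
    "ransac_plane",
    "plane_fit_filter",
    "smooth_mesh_filter",
    "run_outlier_removal",
]

#: sentinel returned by gather_neighborhood for census failures
OUTLIER_MARK = "OUTLIER_MARK"

STAGES = ("P", "P_prime", "P_hat", "P_tilde")


@dataclass(frozen=True)
class CleaningConfig:
    """Tunable parameters of the cleaning cascade.

    A
        Isolated-filter scale: a point is isolated when its nearest neighbour
        is farther than ``A * r`` (r = bounding-box diagonal). Default 0.05.
    M
        Minimum neighbourhood size for the plane fit; census failures are
        removed. Default 80.
    B
        Smooth-mesh filter keeps points within ``B`` standard deviations of
        the point-to-mesh distance distribution. Default 5.
    neighbor_cap
        Upper bound on the local set size (nearest first). Default 100.
    radius_scale
        Multiplier on the neighbourhood-search radius ``r``.  The literal
        radius is the full recomputed bounding-box diagonal — with the cap of
        100 nearest neighbours doing the real work — so 1.0 reproduces the
        published behaviour; smaller values restrict the census to a fraction
        of the cloud extent.
    ransac_iters / ransac_seed
        Random-triple budget and seed of the per-point plane fits; collinear
        triples are rejected and count against the budget.
    smooth_mesh_depth
        Grid depth of the low-resolution surface used by stage 4 (resolution
        2**depth per axis); low depth = very smooth. Default 5.
    sigma_floor
        Absolute floor for the stage-4 standard deviation; ``None`` means
        ``1e-12 * r``, preventing total removal of an exactly-on-surface
        cloud. Units: scene units.
    """

    A: float = 0.05
    M: int = 80
    B: float = 5.0
    neighbor_cap: int = 100
    radius_scale: float = 1.0
    ransac_iters: int = 200
    ransac_seed: int = 0
    smooth_mesh_depth: int = 5
    sigma_floor: float | None = None

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.radius_scale <= 0:
            raise ValueError("A, B and radius_scale must be positive")
        if self.M < 3:
            raise ValueError("M must be >= 3 (a plane needs three points)")
        if self.neighbor_cap < self.M:
            raise ValueError("neighbor_cap must be >= M")
        if self.ransac_iters < 1:
            raise ValueError("ransac_iters must be >= 1")


@dataclass
class PointCloudStage:
    """A labelled point set at one stage of the cascade.

    ``ids`` are the original point identities (sparse-model point ids or
    0..N-1 for bare clouds); ``r`` is the bounding-box diagonal of *this*
    stage's points.
    """

    points: np.ndarray
    ids: np.ndarray
    stage: str
    r: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.ids = np.asarray(self.ids, dtype=np.int64).reshape(-1)
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if len(self.ids) != len(self.points):
            raise ValueError("ids and points must have equal length")

    @classmethod
    def from_points(cls, points: np.ndarray, stage: str = "P", ids: np.ndarray | None = None):
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if ids is None:
            ids = np.arange(len(points))
        return cls(points, ids, stage, bbox_diagonal(points) if len(points) else 0.0)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Plane:
    """A plane {x : normal . x + offset = 0} with unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        if abs(norm - 1.0) > 1e-12:
            object.__setattr__(self, "offset", float(self.offset) / norm)
            n = n / norm
        object.__setattr__(self, "normal", n)

    def distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs(points @ self.normal + self.offset)


@dataclass
class CleaningReport:
    """Bookkeeping of every removal decision across the cascade."""

    removed_per_stage: dict[str, list[int]] = field(default_factory=dict)
    distances: dict[int, float] = field(default_factory=dict)  # id -> plane distance D
    avg_D: float = float("nan")
    sigma: float = float("nan")
    mesh_distances: dict[int, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def all_removed(self) -> list[int]:
        out: list[int] = []
        for stage in STAGES:
            out.extend(self.removed_per_stage.get(stage, []))
        return out

    def to_dict(self) -> dict:
        return {
            "removed_per_stage": {k: [int(i) for i in v] for k, v in self.removed_per_stage.items()},
            "avg_D": float(self.avg_D),
            "sigma": float(self.sigma),
            "params": self.params,
        }


def bbox_diagonal(points: np.ndarray) -> float:
    """Euclidean diagonal of the axis-aligned bounding box of a cloud."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        raise ValueError("bbox_diagonal of an empty cloud is undefined")
    ext = points.max(axis=0) - points.min(axis=0)
    return float(np.linalg.norm(ext))


def remove_isolated(
    points_or_stage: np.ndarray | PointCloudStage, A: float = 0.05
) -> PointCloudStage:
    """Stage 1: drop points whose nearest neighbour is farther than ``A * r``.

    ``r`` is the bounding-box diagonal of the *input* cloud and the
    nearest-neighbour search runs over the input cloud in a single pass
    (removals do not cascade).  The returned stage carries the recomputed
    ``r`` of the survivors.
    """
    stage = (
        points_or_stage
        if isinstance(points_or_stage, PointCloudStage)
        else PointCloudStage.from_points(points_or_stage, "P")
    )
    pts = stage.points
    if len(pts) < 2:
        raise ValueError("remove_isolated requires at least 2 points")
    r_in = bbox_diagonal(pts)
    d_nn, _ = cKDTree(pts).query(pts, k=2)
    keep = d_nn[:, 1] <= A * r_in
    survivors = pts[keep]
    r_out = bbox_diagonal(survivors) if len(survivors) else 0.0
    return PointCloudStage(survivors, stage.ids[keep], "P_prime", r_out)


def gather_neighborhood(
    center_index: int, cloud: PointCloudStage, cfg: CleaningConfig
) -> np.ndarray | str:
    """Local set of one point: in-radius neighbours, capped, or OUTLIER_MARK.

    Neighbours (excluding the centre) within ``radius_scale * r`` of the
    centre; if more than ``neighbor_cap`` qualify only the cap nearest are
    returned; fewer than ``M`` → :data:`OUTLIER_MARK`.  Ties at the cap
    boundary resolve to the lowest point index (deterministic).
    """
    idx = _gather_indices(cloud.points, cKDTree(cloud.points), np.array([center_index]), cfg)[0]
    if idx is None:
        return OUTLIER_MARK
    return cloud.points[idx]


def _cap_nearest(nb: np.ndarray, d: np.ndarray, cap: int) -> np.ndarray:
    """Take the cap nearest indices; ties resolve to the lowest index."""
    order = np.lexsort((nb, d))
    return np.sort(nb[order[:cap]])


def _gather_indices(pts, tree, centers, cfg):
    """Neighbour index lists for several centre indices (None = census fail).

    When the search radius covers the whole bounding-box diagonal every point
    is trivially within radius of every other, so only the nearest-neighbour
    cap matters; that case is answered with batched k-NN queries.
    """
    n = len(pts)
    r = bbox_diagonal(pts)
    radius = cfg.radius_scale * r
    out = []
    if radius >= r:  # all pairwise distances are <= r <= radius
        if n - 1 < cfg.M:
            return [None] * len(centers)
        k = min(n, cfg.neighbor_cap + 2)  # self + cap + one tie candidate
        d, idx = tree.query(pts[centers], k=k)
        d, idx = np.atleast_2d(d), np.atleast_2d(idx)
        for row_d, row_i, ci in zip(d, idx, centers):
            mask = row_i != ci
            nb, nd = row_i[mask], row_d[mask]
            if n - 1 > cfg.neighbor_cap:
                out.append(_cap_nearest(nb, nd, cfg.neighbor_cap))
            else:
                out.append(np.sort(nb))
        return out
    for ci in centers:
        nb = tree.query_ball_point(pts[ci], radius)
        nb = np.asarray([j for j in nb if j != ci], dtype=np.int64)
        if len(nb) < cfg.M:
            out.append(None)
            continue
        if len(nb) > cfg.neighbor_cap:
            dloc = np.linalg.norm(pts[nb] - pts[ci], axis=1)
            out.append(_cap_nearest(nb, dloc, cfg.neighbor_cap))
        else:
            out.append(np.sort(nb))
    return out


def _triple_planes(pts: np.ndarray, triples: np.ndarray):
    """Normals/offsets for index triples; returns (normals, offsets, valid)."""
    a = pts[triples[:, 0]]
    b = pts[triples[:, 1]]
    c = pts[triples[:, 2]]
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1)
    scale = np.max(np.abs(pts)) + 1.0
    valid = norm > 1e-12 * scale * scale
    n = np.where(valid[:, None], n / np.where(norm == 0, 1.0, norm)[:, None], 0.0)
    off = -np.einsum("ij,ij->i", n, a)
    return n, off, valid


def ransac_plane(
    local_points: np.ndarray,
    iters: int = 200,
    seed: int | np.random.Generator = 0,
    eps: float | None = None,
) -> Plane:
    """Best plane through a local point set by random three-point consensus.

    Candidate planes come from ``iters`` random triples (all triples,
    enumerated deterministically, when ``iters`` covers the full C(n,3)
    budget); degenerate (collinear) triples are rejected but consume budget.
    The winner maximises the inlier count at threshold ``eps`` (default
    ``0.01 *`` the local set's bounding-box diagonal — scale-free); ties break
    by the smaller sum of inlier distances, then by draw order.
    """
    pts = np.asarray(local_points, dtype=float).reshape(-1, 3)
    n = len(pts)
    if n < 3:
        raise ValueError("plane fitting requires at least 3 points")
    if eps is None:
        eps = 0.01 * bbox_diagonal(pts)

    n_triples = n * (n - 1) * (n - 2) // 6
    if iters >= n_triples:
        triples = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        draws = rng.integers(0, n, size=(iters, 3))
        distinct = (
            (draws[:, 0] != draws[:, 1]) & (draws[:, 1] != draws[:, 2]) & (draws[:, 0] != draws[:, 2])
        )
        triples = draws[distinct]
        if len(triples) == 0:
            raise ValueError("no valid triple drawn within the iteration budget")

    normals, offsets, valid = _triple_planes(pts, triples)
    if not valid.any():
        raise ValueError("degenerate geometry: all sampled triples are collinear")
    normals, offsets = normals[valid], offsets[valid]

    # distance matrix (candidates x points), chunked for memory
    best_key = None  # (-count, sum_inlier_dist, draw_order): minimise
    best_idx = -1
    chunk = max(1, int(2e6) // max(n, 1))
    for s in range(0, len(normals), chunk):
        N = normals[s : s + chunk]
        O = offsets[s : s + chunk]
        D = np.abs(pts @ N.T + O[None, :])  # (n, c)
        inl = D <= eps
        counts = inl.sum(axis=0)
        sums = np.where(inl, D, 0.0).sum(axis=0)
        j = int(np.lexsort((np.arange(len(N)), sums, -counts))[0])
        key = (-int(counts[j]), float(sums[j]), s + j)
        if best_key is None or key < best_key:
            best_key = key
            best_idx = s + j

    return Plane(normals[best_idx], float(offsets[best_idx]))


def plane_fit_filter(
    cloud: PointCloudStage, cfg: CleaningConfig | None = None
) -> tuple[PointCloudStage, CleaningReport]:
    """Stages 2+3: neighbourhood census, local plane fits, average-distance cut.

    Census failures are removed first and never receive a distance; the mean
    of the recorded distances is computed once over all census survivors, and
    a survivor is removed iff its distance is strictly above that mean.
    Per-point RANSAC draws derive deterministically from ``cfg.ransac_seed``
    and the point's position in the stage, so a fixed seed reproduces the
    removal set bit for bit.
    """
    cfg = cfg or CleaningConfig()
    pts = cloud.points
    n = len(pts)
    if n == 0:
        return replace(cloud, stage="P_hat"), CleaningReport()
    tree = cKDTree(pts)
    neighborhoods = _gather_indices(pts, tree, np.arange(n), cfg)

    census_fail = np.array([nb is None for nb in neighborhoods])
    D = np.full(n, np.nan)
    root = np.random.SeedSequence(cfg.ransac_seed)
    children = root.spawn(n)
    for i in range(n):
        nb = neighborhoods[i]
        if nb is None:
            continue
        local = pts[nb]
        try:
            plane = ransac_plane(
                local, iters=cfg.ransac_iters, seed=np.random.default_rng(children[i])
            )
        except ValueError:
            # fully degenerate neighbourhood geometry: treat as census failure
            census_fail[i] = True
            continue
        D[i] = float(plane.distance(pts[i])[0])

    fitted = ~census_fail
    if not fitted.any():
        warnings.warn("every point failed the neighbourhood census; result is empty")
        avg = float("nan")
        keep = np.zeros(n, dtype=bool)
    else:
        avg = float(np.mean(D[fitted]))
        keep = fitted & ~(D > avg)

    report = CleaningReport(
        removed_per_stage={
            "P_hat": [int(i) for i in cloud.ids[~keep]],
        },
        distances={int(cid): float(d) for cid, d, f in zip(cloud.ids, D, fitted) if f},
        avg_D=avg,
        params={"M": cfg.M, "neighbor_cap": cfg.neighbor_cap, "ransac_iters": cfg.ransac_iters},
    )
    survivors = pts[keep]
    r_out = bbox_diagonal(survivors) if len(survivors) else 0.0
    return PointCloudStage(survivors, cloud.ids[keep], "P_hat", r_out), report


def smooth_mesh_filter(
    cloud: PointCloudStage,
    cfg: CleaningConfig | None = None,
    normals_provider=None,
) -> tuple[PointCloudStage, CleaningReport]:
    """Stage 4: distance-to-smooth-surface cut at ``B`` standard deviations.

    A deliberately low-resolution surface is reconstructed from the cloud
    (implicit signed-distance meshing at ``smooth_mesh_depth``); every point's
    unsigned distance to it is measured, sigma is the population standard
    deviation of that distribution, and points farther than
    ``B * max(sigma, sigma_floor)`` are removed.  ``normals_provider`` maps a
    point array to oriented unit normals; the default estimates normals by
    local PCA and orients them toward the cloud centroid (adequate for a
    star-shaped cavity viewed from inside).
    """
    from . import meshing
    from ._geom import points_to_mesh_distance

    cfg = cfg or CleaningConfig()
    pts = cloud.points
    if len(pts) == 0:
        raise ValueError("smooth_mesh_filter requires a nonempty cloud")

    if normals_provider is None:
        def normals_provider(p):
            nf = meshing.estimate_normals(p, k=min(100, len(p) - 1))
            return meshing.orient_toward_point(p, nf.normals, p.mean(axis=0))

    normals = np.asarray(normals_provider(pts), dtype=float)
    mesh = meshing.reconstruct_surface(pts, normals, depth=cfg.smooth_mesh_depth)
    dist = points_to_mesh_distance(pts, mesh.vertices, mesh.faces)
    sigma = float(dist.std())
    floor = cfg.sigma_floor if cfg.sigma_floor is not None else 1e-12 * max(cloud.r, 1.0)
    keep = dist <= cfg.B * max(sigma, floor)

    report = CleaningReport(
        removed_per_stage={"P_tilde": [int(i) for i in cloud.ids[~keep]]},
        sigma=sigma,
        mesh_distances={int(cid): float(d) for cid, d in zip(cloud.ids, dist)},
        params={"B": cfg.B, "smooth_mesh_depth": cfg.smooth_mesh_depth},
    )
    survivors = pts[keep]
    r_out = bbox_diagonal(survivors) if len(survivors) else 0.0
    return PointCloudStage(survivors, cloud.ids[keep], "P_tilde", r_out), report


def run_outlier_removal(
    recon_or_points,
    cfg: CleaningConfig | None = None,
    normals_provider=None,
) -> tuple[PointCloudStage, CleaningReport]:
    """Run the full cascade P -> P' -> P-hat -> P-tilde.

    Accepts a bare (N, 3) array, a :class:`PointCloudStage`, or a
    :class:`~gastro3d.io_formats.SparseReconstruction` (its points and ids are
    extracted).  The report records every removal with its stage and the
    stage statistics (average plane distance, sigma).
    """
    from .io_formats import SparseReconstruction

    cfg = cfg or CleaningConfig()
    if isinstance(recon_or_points, SparseReconstruction):
        xyz, ids = recon_or_points.point_array()
        stage0 = PointCloudStage(xyz, ids, "P", bbox_diagonal(xyz))
    elif isinstance(recon_or_points, PointCloudStage):
        stage0 = recon_or_points
    else:
        stage0 = PointCloudStage.from_points(recon_or_points, "P")

    p_prime = remove_isolated(stage0, cfg.A)
    removed_isolated = sorted(set(stage0.ids.tolist()) - set(p_prime.ids.tolist()))

    p_hat, rep_plane = plane_fit_filter(p_prime, cfg)
    if len(p_hat) == 0:
        warnings.warn("plane-fit filter removed every point; skipping smooth-mesh stage")
        report = CleaningReport(
            removed_per_stage={
                "P_prime": removed_isolated,
                "P_hat": rep_plane.removed_per_stage.get("P_hat", []),
                "P_tilde": [],
            },
            distances=rep_plane.distances,
            avg_D=rep_plane.avg_D,
            params=_params_dict(cfg),
        )
        return p_hat, report

    p_tilde, rep_mesh = smooth_mesh_filter(p_hat, cfg, normals_provider)

    report = CleaningReport(
        removed_per_stage={
            "P_prime": removed_isolated,
            "P_hat": rep_plane.removed_per_stage.get("P_hat", []),
            "P_tilde": rep_mesh.removed_per_stage.get("P_tilde", []),
        },
        distances=rep_plane.distances,
        avg_D=rep_plane.avg_D,
        sigma=rep_mesh.sigma,
        mesh_distances=rep_mesh.mesh_distances,
        params=_params_dict(cfg),
    )
    return p_tilde, report


def _params_dict(cfg: CleaningConfig) -> dict:
    return {
        "A": cfg.A,
        "M": cfg.M,
        "B": cfg.B,
        "neighbor_cap": cfg.neighbor_cap,
        "radius_scale": cfg.radius_scale,
        "ransac_iters": cfg.ransac_iters,
        "ransac_seed": cfg.ransac_seed,
        "smooth_mesh_depth": cfg.smooth_mesh_depth,
    }
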