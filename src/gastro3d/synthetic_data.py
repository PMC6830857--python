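"""Fully labeled synthetic scenes for exercising every pipeline stage.

Endoscope recordings of real patients are not redistributable, so the package
ships a generator that emulates the geometry the pipeline consumes: a closed,
bumpy, star-shaped cavity (an ellipsoid with smooth radial bumps standing in
for the stomach with its rugae), a noisy surface point cloud with planted
isolated and near-surface outliers, an interior camera loop with per-point
visibility tracks exported as a sparse SfM model, and procedural frame
sequences with planted duplicate runs.

The star-shaped radial parameterisation R(u) keeps an exact analytic signed
distance available, so every planted label and every downstream
precision/recall figure is well defined by construction.  Anatomical realism
is explicitly not the goal.

Default conditions (scene units are arbitrary SfM units): semi-axes
(1.0, 0.75, 0.6) — stomach-like proportions; surface noise sigma 0.01 (about
0.4% of the cloud extent, typical bundle-adjusted triangulation jitter);
bump amplitude 0.08 for rugae-like relief; near outliers at radial offsets of
5-15 noise sigmas; isolated outliers planted farther than ``0.05 * r`` from
every other point so the stage-1 oracle is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .frame_preprocess import FrameSequence
from .io_formats import CameraIntrinsics, FramePose, Point3D, SparseReconstruction, rotmat_to_quat

__all__ = [
    "PointLabel",
    "BumpySurface",
    "SyntheticScene",
    "DuplicateSpec",
    "make_surface",
    "sample_cloud",
    "make_trajectory_and_tracks",
    "make_frame_sequence",
    "small_scene",
    "default_scene",
]


class PointLabel(IntEnum):
    INLIER = 0
    ISOLATED_OUTLIER = 1
    NEAR_OUTLIER = 2


@dataclass
class BumpySurface:
    """Closed star-shaped surface: ellipsoid radius modulated by smooth bumps.

    Radius along unit direction u: ``R(u) = r_ell(u) * (1 + amplitude * b(u))``
    where ``b(u)`` sums Gaussian bumps of the angular distance to fixed bump
    directions.  ``signed_distance`` is the radial gauge ``|x| - R(x/|x|)``:
    negative inside the cavity, zero on the surface — exact for radial
    perturbations, which is how the generator plants its labels.
    """

    semi_axes: tuple[float, float, float] = (1.0, 0.75, 0.6)
    bump_amplitude: float = 0.08
    bump_count: int = 12
    seed: int = 0
    bump_dirs: np.ndarray = field(init=False)
    bump_widths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0 <= self.bump_amplitude < 1:
            raise ValueError("bump_amplitude must be in [0, 1) to avoid self-intersection")
        rng = np.random.default_rng(self.seed)
        d = rng.normal(size=(max(self.bump_count, 1), 3))
        self.bump_dirs = d / np.linalg.norm(d, axis=1, keepdims=True)
        self.bump_widths = rng.uniform(0.2, 0.5, size=max(self.bump_count, 1))

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        """Surface radius along unit directions (N, 3)."""
        u = np.atleast_2d(np.asarray(dirs, dtype=float))
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        a, b, c = self.semi_axes
        r_ell = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)
        if self.bump_amplitude == 0 or self.bump_count == 0:
            return r_ell
        cosang = np.clip(u @ self.bump_dirs.T, -1.0, 1.0)
        ang = np.arccos(cosang)  # (N, K)
        bumps = np.exp(-0.5 * (ang / self.bump_widths[None, :]) ** 2).sum(axis=1)
        bumps = bumps / max(self.bump_count, 1)  # normalised: total modulation < amplitude
        return r_ell * (1.0 + self.bump_amplitude * bumps)

    def surface_points(self, dirs: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(dirs, dtype=float))
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        return self.radius(u)[:, None] * u

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Radial signed distance: < 0 inside, 0 on surface, > 0 outside."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        norm = np.linalg.norm(p, axis=1)
        out = np.empty(len(p))
        at_center = norm == 0
        out[at_center] = -min(self.semi_axes)
        safe = ~at_center
        if safe.any():
            u = p[safe] / norm[safe, None]
            out[safe] = norm[safe] - self.radius(u)
        return out

    def area_estimate(self, subdivisions: int = 5) -> float:
        """Surface area by radially mapping a dense icosphere triangulation."""
        import trimesh

        ico = trimesh.creation.icosphere(subdivisions=subdivisions)
        verts = self.surface_points(np.asarray(ico.vertices))
        tri = verts[np.asarray(ico.faces)]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(n, axis=1).sum())


def make_surface(
    semi_axes: tuple[float, float, float] = (1.0, 0.75, 0.6),
    bump_amplitude: float = 0.08,
    bump_count: int = 12,
    seed: int = 0,
) -> BumpySurface:
    """Construct the cavity surface (see :class:`BumpySurface`)."""
    return BumpySurface(semi_axes, bump_amplitude, bump_count, seed)


@dataclass
class SyntheticScene:
    """A labeled point cloud on a known surface, optionally with cameras."""

    surface: BumpySurface
    points: np.ndarray
    labels: np.ndarray  # PointLabel values, aligned with points
    noise_sigma: float
    seed: int
    recon: SparseReconstruction | None = None

    @property
    def inlier_mask(self) -> np.ndarray:
        return self.labels == PointLabel.INLIER

    @property
    def outlier_mask(self) -> np.ndarray:
        return self.labels != PointLabel.INLIER


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_cloud(
    surface: BumpySurface,
    n_inliers: int = 5000,
    noise_sigma: float = 0.01,
    n_isolated: int = 500,
    n_near: int = 500,
    near_scale: float = 1.0,
    seed: int = 0,
    isolation_A: float = 0.05,
    max_tries: int = 400,
) -> SyntheticScene:
    """Sample a labeled cloud: noisy surface inliers plus planted outliers.

    Inliers are uniform-direction surface samples with radial Gaussian noise.
    Near outliers sit at radial offsets of magnitude uniform in
    ``[5, 15] * noise_sigma * near_scale`` (either side of the wall).
    Isolated outliers are rejection-sampled in a box grown 25% beyond the
    cloud so that each lies farther than ``isolation_A * (expanded box
    diagonal)`` from every other point; since the final cloud stays inside
    that box, the planted distance strictly exceeds ``isolation_A * r`` of
    the assembled cloud — the label contract is verified exhaustively before
    returning.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    pieces, labels = [], []

    dirs = _uniform_sphere(rng, n_inliers)
    radii = surface.radius(dirs) + rng.normal(0.0, noise_sigma, size=n_inliers)
    pieces.append(radii[:, None] * dirs)
    labels.append(np.full(n_inliers, PointLabel.INLIER))

    if n_near:
        dirs = _uniform_sphere(rng, n_near)
        mag = rng.uniform(5.0, 15.0, size=n_near) * noise_sigma * near_scale
        sign = rng.choice([-1.0, 1.0], size=n_near)
        radii = surface.radius(dirs) + sign * mag
        pieces.append(radii[:, None] * dirs)
        labels.append(np.full(n_near, PointLabel.NEAR_OUTLIER))

    base = np.concatenate(pieces) if pieces else np.zeros((0, 3))
    if n_isolated:
        if len(base) == 0:
            base = np.array([[-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]]) * max(surface.semi_axes)
        lo, hi = base.min(axis=0), base.max(axis=0)
        margin = 0.25 * (hi - lo)
        lo_e, hi_e = lo - margin, hi + margin
        diag_e = float(np.linalg.norm(hi_e - lo_e))
        min_dist = isolation_A * diag_e * 1.02
        accepted: list[np.ndarray] = []
        tree = cKDTree(base)
        tries = 0
        while len(accepted) < n_isolated:
            if tries >= max_tries * n_isolated:
                raise RuntimeError("isolated-outlier rejection sampling exceeded retry budget")
            tries += 1
            cand = rng.uniform(lo_e, hi_e)
            if tree.query(cand)[0] <= min_dist:
                continue
            if accepted and np.min(np.linalg.norm(np.array(accepted) - cand, axis=1)) <= min_dist:
                continue
            accepted.append(cand)
        pieces.append(np.array(accepted))
        labels.append(np.full(n_isolated, PointLabel.ISOLATED_OUTLIER))

    points = np.concatenate(pieces)
    labels = np.concatenate(labels).astype(np.int64)

    if n_isolated:  # verify the planted contract exhaustively
        ext = points.max(axis=0) - points.min(axis=0)
        r = float(np.linalg.norm(ext))
        d_nn = cKDTree(points).query(points, k=2)[0][:, 1]
        iso = labels == PointLabel.ISOLATED_OUTLIER
        if not np.all(d_nn[iso] > isolation_A * r):
            raise RuntimeError("isolated-outlier distance contract violated at generation time")

    return SyntheticScene(surface, points, labels, noise_sigma, seed)


def _look_at_rotation(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation with +z toward the target (x right, y down)."""
    forward = target - center
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    if abs(forward @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    return np.stack([right, down, forward])  # rows


def make_trajectory_and_tracks(
    surface: BumpySurface,
    scene: SyntheticScene,
    n_cameras: int = 30,
    points_per_view: int = 300,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    fov_deg: float = 100.0,
) -> SparseReconstruction:
    """Interior camera loop with per-point visibility tracks.

    Cameras ride a smooth closed loop at 45% of the local cavity radius,
    looking outward at the wall with cycling pitch so the whole surface is
    covered.  Each camera observes its ``points_per_view`` nearest in-view
    scene points; any point left with fewer than two observations is assigned
    to the two cameras facing it most directly (idealised visibility — the
    tracks exercise bookkeeping, not photometrics).  The result passes full
    referential-integrity validation.
    """
    if n_cameras < 2:
        raise ValueError("a trajectory needs at least 2 cameras")
    w, h = image_size
    f = w / (2.0 * np.tan(np.deg2rad(fov_deg) / 2.0))
    cam = CameraIntrinsics(1, "PINHOLE", w, h, np.array([f, f, w / 2.0, h / 2.0]))

    recon = SparseReconstruction(cameras={1: cam})
    pts = scene.points
    npts = len(pts)

    ts = np.linspace(0.0, 2.0 * np.pi, n_cameras, endpoint=False)
    pitches = np.array([0.0, 0.7, -0.7])
    centers, rotations = [], []
    for i, t in enumerate(ts):
        u = np.array([np.cos(t), np.sin(t), 0.3 * np.sin(2 * t)])
        u /= np.linalg.norm(u)
        center = 0.45 * surface.radius(u[None])[0] * u
        if surface.signed_distance(center[None])[0] >= 0:
            raise RuntimeError("camera center fell outside the cavity")
        look_dir = u + np.array([0.0, 0.0, pitches[i % len(pitches)]])
        look_dir /= np.linalg.norm(look_dir)
        target = surface.surface_points(look_dir[None])[0]
        centers.append(center)
        rotations.append(_look_at_rotation(center, target))

    # choose observations per camera: nearest in-view points
    obs_per_frame: dict[int, list[int]] = {}
    for i in range(n_cameras):
        R, c = rotations[i], centers[i]
        xyz_cam = (pts - c) @ R.T
        uv = cam.project(xyz_cam)
        visible = (
            (xyz_cam[:, 2] > 0)
            & ~np.isnan(uv[:, 0])
            & (uv[:, 0] >= 0) & (uv[:, 0] < w)
            & (uv[:, 1] >= 0) & (uv[:, 1] < h)
        )
        cand = np.flatnonzero(visible)
        order = np.argsort(np.linalg.norm(pts[cand] - c, axis=1), kind="stable")
        obs_per_frame[i + 1] = cand[order[:points_per_view]].tolist()

    # guarantee every point is tracked by >= 2 cameras
    count = np.zeros(npts, dtype=int)
    for lst in obs_per_frame.values():
        for j in lst:
            count[j] += 1
    centers_arr = np.array(centers)
    forwards = np.array([R[2] for R in rotations])
    for j in np.flatnonzero(count < 2):
        to_pt = pts[j] - centers_arr
        to_pt /= np.linalg.norm(to_pt, axis=1, keepdims=True)
        align = np.einsum("ij,ij->i", forwards, to_pt)
        for fi in np.argsort(-align):
            fid = int(fi) + 1
            if j not in obs_per_frame[fid]:
                obs_per_frame[fid].append(int(j))
                count[j] += 1
            if count[j] >= 2:
                break

    rng = np.random.default_rng(seed)
    colors = rng.integers(60, 200, size=(npts, 3)).astype(np.uint8)
    tracks: dict[int, list[tuple[int, int]]] = {j: [] for j in range(npts)}
    for fid in range(1, n_cameras + 1):
        R, c = rotations[fid - 1], centers[fid - 1]
        idx = obs_per_frame[fid]
        xyz_cam = (pts[idx] - c) @ R.T
        uv = cam.project(xyz_cam)
        pose = FramePose(
            frame_id=fid,
            qvec=rotmat_to_quat(R),
            tvec=-R @ c,
            camera_id=1,
            name=f"frame{fid:06d}.png",
            xys=uv,
            point3d_ids=np.asarray(idx, dtype=np.int64),
        )
        recon.frames[fid] = pose
        for oi, j in enumerate(idx):
            tracks[j].append((fid, oi))

    for j in range(npts):
        recon.points[j] = Point3D(
            point_id=j,
            xyz=pts[j],
            color=colors[j],
            reproj_error=float(abs(rng.normal(0.0, 0.5))),
            track=tracks[j],
        )
    recon.validate()
    scene.recon = recon
    return recon


@dataclass
class DuplicateSpec:
    """Layout of planted duplicate runs in a procedural frame sequence.

    ``duplicate_runs`` are disjoint ``(start_index, run_length)`` spans of
    bit-identical frames; between distinct frames exactly
    ``perturbation_fraction`` of the pixels are redrawn, which must exceed
    the dedup threshold phi under test or the fixture would be ambiguous.
    """

    n_frames: int = 200
    duplicate_runs: list[tuple[int, int]] = field(default_factory=list)
    perturbation_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.perturbation_fraction <= 1:
            raise ValueError("perturbation_fraction must be in (0, 1]")
        runs = sorted(self.duplicate_runs)
        for (s, l) in runs:
            if l < 1 or s < 0 or s + l > self.n_frames:
                raise ValueError(f"run ({s}, {l}) is out of range")
        for (s1, l1), (s2, _) in zip(runs, runs[1:]):
            if s1 + l1 > s2:
                raise ValueError("duplicate runs must be disjoint")
        self.duplicate_runs = runs

    def validate_against(self, phi: float) -> None:
        if self.perturbation_fraction <= phi:
            raise ValueError(
                f"perturbation_fraction {self.perturbation_fraction} must exceed phi {phi}"
            )

    def ground_truth_kept(self) -> list[int]:
        """First frame of every run plus all singleton frames."""
        dup_members = set()
        for s, l in self.duplicate_runs:
            dup_members.update(range(s + 1, s + l))
        return [i for i in range(self.n_frames) if i not in dup_members]


def make_frame_sequence(
    spec: DuplicateSpec,
    width: int = 64,
    height: int = 64,
    seed: int = 0,
    phi: float | None = None,
) -> tuple[FrameSequence, list[int]]:
    """Procedural noise frames with planted exact-duplicate runs.

    Within a run frames are bit-identical copies of the run head; between
    consecutive distinct frames exactly ``perturbation_fraction`` of the
    pixels are redrawn to guaranteed-different values.  When ``phi`` is given
    the spec is validated against it first.  Returns the sequence and the
    ground-truth kept indices.
    """
    if phi is not None:
        spec.validate_against(phi)
    rng = np.random.default_rng(seed)
    npix = width * height
    n_changed = int(round(spec.perturbation_fraction * npix))

    run_head = {}
    for s, l in spec.duplicate_runs:
        for i in range(s, s + l):
            run_head[i] = s

    frames: list[np.ndarray] = []
    prev_distinct = None
    for i in range(spec.n_frames):
        head = run_head.get(i, i)
        if head != i:
            frames.append(frames[head].copy())
            continue
        if prev_distinct is None:
            img = rng.integers(0, 256, size=(height, width), dtype=np.uint8)
        else:
            img = frames[prev_distinct].copy()
            flat = img.reshape(-1)
            pos = rng.choice(npix, size=n_changed, replace=False)
            delta = rng.integers(1, 256, size=n_changed).astype(np.uint8)
            flat[pos] = (flat[pos].astype(np.int16) + delta) % 256
        frames.append(img)
        prev_distinct = i

    seq = FrameSequence(frames=frames, channel="R", source_id=f"synthetic-{seed}")
    return seq, spec.ground_truth_kept()


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def small_scene(seed: int = 0, with_cameras: bool = True) -> SyntheticScene:
    """A fast scene for unit tests and smoke runs (hundreds of points)."""
    surface = make_surface(seed=seed)
    scene = sample_cloud(
        surface, n_inliers=800, noise_sigma=0.01, n_isolated=60, n_near=60, seed=seed
    )
    if with_cameras:
        make_trajectory_and_tracks(surface, scene, n_cameras=16, points_per_view=150, seed=seed)
    return scene


def default_scene(seed: int = 0, with_cameras: bool = True) -> SyntheticScene:
    """The reference study scene: 5000 inliers, 500 isolated, 500 near outliers."""
    surface = make_surface(seed=seed)
    scene = sample_cloud(
        surface, n_inliers=5000, noise_sigma=0.01, n_isolated=500, n_near=500, seed=seed
    )
    if with_cameras:
        make_trajectory_and_tracks(surface, scene, n_cameras=30, points_per_view=300, seed=seed)
    return scene
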