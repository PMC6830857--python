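"""Frame localization on the organ mesh and similarity-based frame retrieval.

Retrieval follows the classic global-descriptor recipe: every frame is mapped
to a fixed-length vector f(I) and frames are ranked by the Euclidean distance
d = ||f(I_r) - f(I_t)|| to a chosen reference frame.  The descriptor is
pluggable: the default ("downsample") is a deterministic, dependency-free
16x16 grayscale thumbnail, mean-subtracted and L2-normalised — adequate for
near-duplicate and same-region retrieval.  Externally computed CNN
descriptors (e.g. from a place-recognition network) can be plugged in either
by registering a callable or by loading one vector per frame from a JSON
file; the ranking contract is identical.

Localization casts a grid of pixel rays from a registered frame's camera and
records the first mesh intersections — the frame's visual footprint on the
reconstructed surface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geom import ray_mesh_first_hit
from .frame_preprocess import FrameSequence
from .io_formats import SparseReconstruction, TriangleMesh

__all__ = [
    "ImageDescriptor",
    "RetrievalResult",
    "FrameFootprint",
    "compute_descriptor",
    "register_descriptor",
    "load_descriptor_bank",
    "retrieve_similar",
    "localize_frame",
    "select_local_frames",
]


@dataclass(frozen=True)
class ImageDescriptor:
    vector: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float).reshape(-1)
        if not np.all(np.isfinite(v)):
            raise ValueError("descriptor entries must be finite")
        object.__setattr__(self, "vector", v)


@dataclass
class RetrievalResult:
    """Frames ranked by ascending descriptor distance to the reference."""

    ranked: list[tuple[int, float]]  # (frame index, distance)
    reference_id: int

    def __post_init__(self) -> None:
        d = [x[1] for x in self.ranked]
        if any(b < a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be non-decreasing down the ranking")

    def ids(self) -> list[int]:
        return [fid for fid, _ in self.ranked]


@dataclass
class FrameFootprint:
    """First-hit points of a frame's pixel rays on the mesh."""

    frame_id: int
    hit_points: np.ndarray  # (H, 3)
    hit_faces: np.ndarray  # (H,)
    coverage_fraction: float


def _downsample_descriptor(frame: np.ndarray, size: int = 16) -> np.ndarray:
    from skimage.transform import resize

    img = np.asarray(frame, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    thumb = resize(img, (size, size), anti_aliasing=True, preserve_range=True)
    v = thumb.ravel()
    v = v - v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:  # constant image: descriptor is the zero vector
        return v
    return v / norm


_DESCRIPTOR_METHODS: dict[str, callable] = {"downsample": _downsample_descriptor}


def register_descriptor(name: str, fn) -> None:
    """Register a custom descriptor callable ``frame -> 1-D vector``."""
    _DESCRIPTOR_METHODS[name] = fn


def load_descriptor_bank(path: str | Path, name: str = "external") -> str:
    """Register precomputed per-frame descriptors from a JSON file.

    The file maps frame index (as string or int) to a vector.  The registered
    method ignores pixel content and looks frames up by their sequence index,
    letting users substitute CNN descriptors without this package shipping a
    trained model.  Returns the registered method name.
    """
    with open(path) as fh:
        raw = json.load(fh)
    bank = {int(k): np.asarray(v, dtype=float) for k, v in raw.items()}
    sizes = {v.size for v in bank.values()}
    if len(sizes) > 1:
        raise ValueError(f"descriptor vectors have mixed lengths: {sorted(sizes)}")

    def lookup(frame, _index=None, _bank=bank):
        if _index is None or _index not in _bank:
            raise KeyError(f"no external descriptor for frame index {_index}")
        return _bank[_index]

    _DESCRIPTOR_METHODS[name] = lookup
    return name


def compute_descriptor(frame: np.ndarray, method: str = "downsample", index: int | None = None) -> ImageDescriptor:
    """Descriptor vector of one frame; deterministic for a given method."""
    if method not in _DESCRIPTOR_METHODS:
        raise ValueError(
            f"unsupported descriptor method {method!r}; known: {sorted(_DESCRIPTOR_METHODS)}"
        )
    fn = _DESCRIPTOR_METHODS[method]
    try:
        vec = fn(frame, _index=index)  # bank-style methods accept the index
    except TypeError:
        vec = fn(frame)
    return ImageDescriptor(np.asarray(vec, dtype=float).reshape(-1), method)


def retrieve_similar(
    reference_id: int, seq: FrameSequence, N: int = 100, method: str = "downsample"
) -> RetrievalResult:
    """Top-N frames by Euclidean descriptor distance to the reference.

    The reference frame itself ranks first at distance 0.  ``N`` above the
    sequence length is clamped with a warning; ties break by frame index.
    The published operating value is N = 100.
    """
    if reference_id not in seq.indices:
        raise KeyError(f"reference frame {reference_id} is not in the sequence")
    if N > len(seq):
        warnings.warn(f"N={N} exceeds sequence length {len(seq)}; clamping")
        N = len(seq)
    descs = np.stack(
        [compute_descriptor(f, method, index=i).vector for i, f in zip(seq.indices, seq.frames)]
    )
    ref_pos = seq.indices.index(reference_id)
    dist = np.linalg.norm(descs - descs[ref_pos], axis=1)
    sort_dist = dist.copy()
    sort_dist[ref_pos] = -1.0  # the reference always ranks first
    order = np.lexsort((np.asarray(seq.indices), sort_dist))[:N]
    ranked = [(int(seq.indices[i]), float(dist[i])) for i in order]
    return RetrievalResult(ranked=ranked, reference_id=reference_id)


def localize_frame(
    frame_id: int,
    recon: SparseReconstruction,
    mesh: TriangleMesh,
    ray_grid: int = 32,
) -> FrameFootprint:
    """Project a registered frame's view onto the mesh by ray casting.

    A ``ray_grid x ray_grid`` grid of pixel-centre rays is cast from the
    camera through the image plane; first hits are recorded and
    ``coverage_fraction`` is hits / rays.  Rays starting inside a closed mesh
    are valid — the endoscope films from inside the cavity.
    """
    fr = recon.frames.get(frame_id)
    if fr is None:
        raise KeyError(f"frame {frame_id} is not registered in the reconstruction")
    cam = recon.cameras[fr.camera_id]
    fx, fy = cam.focal
    cx, cy = cam.principal_point

    us = (np.arange(ray_grid) + 0.5) * cam.width / ray_grid
    vs = (np.arange(ray_grid) + 0.5) * cam.height / ray_grid
    uu, vv = np.meshgrid(us, vs, indexing="xy")
    dirs_cam = np.stack(
        [(uu.ravel() - cx) / fx, (vv.ravel() - cy) / fy, np.ones(ray_grid * ray_grid)], axis=1
    )
    R = fr.rotation_matrix
    dirs_world = dirs_cam @ R  # R^T @ d, row-wise
    dirs_world /= np.linalg.norm(dirs_world, axis=1, keepdims=True)
    origin = fr.camera_center
    origins = np.tile(origin, (len(dirs_world), 1))

    hit, locs, faces = ray_mesh_first_hit(origins, dirs_world, mesh.vertices, mesh.faces)
    return FrameFootprint(
        frame_id=frame_id,
        hit_points=locs[hit],
        hit_faces=faces[hit],
        coverage_fraction=float(hit.sum()) / len(hit),
    )


def select_local_frames(
    reference_id: int, seq: FrameSequence, N: int = 100, method: str = "downsample"
) -> list[int]:
    """Frame ids to feed a local reconstruction around the reference frame.

    The ids are exactly the retrieval ranking prefix; callers export the
    corresponding single-channel frames and re-run the external SfM tool on
    them (local reconstruction is orchestration, not computation, here).
    """
    return retrieve_similar(reference_id, seq, N=N, method=method).ids()
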