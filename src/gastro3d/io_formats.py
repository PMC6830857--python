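"""Shared geometric types and I/O for standard sparse-reconstruction formats.

The pipeline interoperates with the ubiquitous three-file text layout of
sparse structure-from-motion models (``cameras.txt`` / ``images.txt`` /
``points3D.txt``), with PLY point clouds and triangle meshes (ascii and
binary little-endian dialects), and with plain image-frame directories.

Conventions
-----------
* Quaternions are stored ``(w, x, y, z)`` and map world to camera:
  ``x_cam = R(q) @ x_world + t``.
* Pixel coordinates have their origin at the top-left, x right, y down, and
  are passed through verbatim (no half-pixel re-centering).
* Scene units are arbitrary reconstruction units; no metric scale is ever
  attached.
* Only the text dialect of the sparse model is supported; the binary dialect
  is a possible extension.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frame_preprocess import FrameSequence

__all__ = [
    "CameraIntrinsics",
    "FramePose",
    "Point3D",
    "SparseReconstruction",
    "TriangleMesh",
    "FormatError",
    "IntegrityError",
    "read_colmap_sparse",
    "write_colmap_sparse",
    "read_ply_points",
    "write_ply_points",
    "read_ply_mesh",
    "write_ply_mesh",
    "read_frame_dir",
]

#: parameter layout (names) per supported camera model, as in the text dialect
CAMERA_MODELS: dict[str, tuple[str, ...]] = {
    "SIMPLE_PINHOLE": ("f", "cx", "cy"),
    "PINHOLE": ("fx", "fy", "cx", "cy"),
    "SIMPLE_RADIAL": ("f", "cx", "cy", "k"),
    "RADIAL": ("f", "cx", "cy", "k1", "k2"),
    "OPENCV": ("fx", "fy", "cx", "cy", "k1", "k2", "p1", "p2"),
    "OPENCV_FISHEYE": ("fx", "fy", "cx", "cy", "k1", "k2", "k3", "k4"),
}

INVALID_POINT3D = -1  # sentinel for an observation with no triangulated point


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(ValueError):
    """Cross-references between records of a sparse model are inconsistent."""


@dataclass
class CameraIntrinsics:
    """Intrinsics of one physical camera in the sparse-model dialect.

    ``params`` follows the model's canonical ordering (see ``CAMERA_MODELS``).
    Distortion handling itself is out of scope here — calibration is performed
    upstream and frames are assumed undistorted where projection is needed.
    """

    camera_id: int
    model_name: str
    width: int
    height: int
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.model_name not in CAMERA_MODELS:
            raise FormatError(f"unknown camera model {self.model_name!r}")
        expected = len(CAMERA_MODELS[self.model_name])
        if self.params.size != expected:
            raise FormatError(
                f"{self.model_name} expects {expected} params, got {self.params.size}"
            )
        fx, fy = self.focal
        cx, cy = self.principal_point
        if fx <= 0 or fy <= 0:
            raise ValueError("focal length must be positive")
        if not (0 <= cx < self.width and 0 <= cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def _names(self) -> tuple[str, ...]:
        return CAMERA_MODELS[self.model_name]

    def _get(self, name: str) -> float:
        return float(self.params[self._names.index(name)])

    @property
    def focal(self) -> tuple[float, float]:
        if "f" in self._names:
            f = self._get("f")
            return f, f
        return self._get("fx"), self._get("fy")

    @property
    def principal_point(self) -> tuple[float, float]:
        return self._get("cx"), self._get("cy")

    @property
    def distortion(self) -> np.ndarray:
        skip = {"f", "fx", "fy", "cx", "cy"}
        idx = [i for i, n in enumerate(self._names) if n not in skip]
        return self.params[idx]

    def project(self, xyz_cam: np.ndarray) -> np.ndarray:
        """Pinhole projection of camera-frame points (N, 3) to pixels (N, 2).

        Uses only the pinhole part of the model (frames assumed undistorted).
        Points with non-positive depth project to NaN.
        """
        xyz_cam = np.atleast_2d(np.asarray(xyz_cam, dtype=float))
        fx, fy = self.focal
        cx, cy = self.principal_point
        z = xyz_cam[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = fx * xyz_cam[:, 0] / z + cx
            v = fy * xyz_cam[:, 1] / z + cy
        uv = np.stack([u, v], axis=1)
        uv[z <= 0] = np.nan
        return uv


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = np.asarray(q, dtype=float)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotmat_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a rotation matrix, w >= 0."""
    R = np.asarray(R, dtype=float)
    K = (
        np.array(
            [
                [R[0, 0] - R[1, 1] - R[2, 2], 0, 0, 0],
                [R[0, 1] + R[1, 0], R[1, 1] - R[0, 0] - R[2, 2], 0, 0],
                [R[0, 2] + R[2, 0], R[1, 2] + R[2, 1], R[2, 2] - R[0, 0] - R[1, 1], 0],
                [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1], R[0, 0] + R[1, 1] + R[2, 2]],
            ]
        )
        / 3.0
    )
    vals, vecs = np.linalg.eigh(K)
    x, y, z, w = vecs[:, np.argmax(vals)]
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q / np.linalg.norm(q)


@dataclass
class FramePose:
    """World-to-camera pose of one registered frame plus its 2D observations.

    ``xys`` is (O, 2) pixel coordinates; ``point3d_ids`` is (O,) integer ids
    into the owning reconstruction's points, with -1 marking an observation
    that was never triangulated.
    """

    frame_id: int
    qvec: np.ndarray  # (w, x, y, z), world -> camera
    tvec: np.ndarray
    camera_id: int
    name: str = ""
    xys: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    point3d_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.qvec = np.asarray(self.qvec, dtype=float)
        self.tvec = np.asarray(self.tvec, dtype=float)
        self.xys = np.asarray(self.xys, dtype=float).reshape(-1, 2)
        self.point3d_ids = np.asarray(self.point3d_ids, dtype=np.int64)
        if self.qvec.shape != (4,) or self.tvec.shape != (3,):
            raise ValueError("qvec must be length 4 and tvec length 3")
        if abs(np.linalg.norm(self.qvec) - 1.0) > 1e-9:
            raise ValueError(f"quaternion of frame {self.frame_id} is not unit-norm")
        if self.point3d_ids.shape[0] != self.xys.shape[0]:
            raise ValueError("xys and point3d_ids must have equal length")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return quat_to_rotmat(self.qvec)

    @property
    def camera_center(self) -> np.ndarray:
        """Camera position in world coordinates, -R^T t."""
        return -self.rotation_matrix.T @ self.tvec

    def world_to_camera(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.rotation_matrix.T + self.tvec


@dataclass
class Point3D:
    """One triangulated scene point with its feature track."""

    point_id: int
    xyz: np.ndarray
    color: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.uint8))
    reproj_error: float = 0.0
    track: list[tuple[int, int]] = field(default_factory=list)  # (frame_id, obs index)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        self.color = np.asarray(self.color, dtype=np.uint8).reshape(3)
        if self.reproj_error < 0:
            raise ValueError("reprojection error must be >= 0")
        self.track = [(int(f), int(o)) for f, o in self.track]


@dataclass
class SparseReconstruction:
    """A sparse SfM model: cameras, registered frame poses, and 3D points.

    Frame observations and point tracks are mutually inverse indices; use
    :meth:`validate` to check the cross-links after manual edits.
    """

    cameras: dict[int, CameraIntrinsics] = field(default_factory=dict)
    frames: dict[int, FramePose] = field(default_factory=dict)
    points: dict[int, Point3D] = field(default_factory=dict)

    def validate(self) -> None:
        for fid, fr in self.frames.items():
            if fr.camera_id not in self.cameras:
                raise IntegrityError(f"frame {fid} references unknown camera {fr.camera_id}")
            for oi, pid in enumerate(fr.point3d_ids):
                if pid == INVALID_POINT3D:
                    continue
                pt = self.points.get(int(pid))
                if pt is None:
                    raise IntegrityError(f"frame {fid} observation {oi} references missing point {pid}")
                if (fid, oi) not in pt.track:
                    raise IntegrityError(
                        f"observation ({fid}, {oi}) -> point {pid} has no inverse track entry"
                    )
        for pid, pt in self.points.items():
            for fid, oi in pt.track:
                fr = self.frames.get(fid)
                if fr is None:
                    raise IntegrityError(f"point {pid} track references unregistered frame {fid}")
                if oi < 0 or oi >= fr.point3d_ids.shape[0]:
                    raise IntegrityError(f"point {pid} track entry ({fid}, {oi}) is out of range")
                if int(fr.point3d_ids[oi]) != pid:
                    raise IntegrityError(
                        f"point {pid} track entry ({fid}, {oi}) does not back-reference the point"
                    )

    def point_array(self) -> tuple[np.ndarray, np.ndarray]:
        """All point coordinates (N, 3) and their ids (N,), sorted by id."""
        ids = np.array(sorted(self.points), dtype=np.int64)
        xyz = np.array([self.points[i].xyz for i in ids], dtype=float).reshape(-1, 3)
        return xyz, ids

    def num_observations(self) -> int:
        return int(sum((fr.point3d_ids != INVALID_POINT3D).sum() for fr in self.frames.values()))


@dataclass
class TriangleMesh:
    """An indexed triangle mesh with optional per-vertex normals and colors."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    vertex_colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        nv = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= nv):
            raise ValueError("face indices out of range")
        if self.faces.size:
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate face with repeated vertex index")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float).reshape(nv, 3)
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.uint8).reshape(nv, 3)

    @property
    def bbox_diagonal(self) -> float:
        if len(self.vertices) == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            lens = np.linalg.norm(n, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            n = n / lens
        return n

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        fn = self.face_normals(normalize=False)  # magnitude = 2 * area
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        lens = np.linalg.norm(vn, axis=1, keepdims=True)
        lens[lens == 0] = 1.0
        return vn / lens


# ---------------------------------------------------------------------------
# Sparse text model
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:.17g}"


def _fmt(x: float) -> str:
    return _FLOAT_FMT.format(float(x))


def read_colmap_sparse(path: str | Path) -> SparseReconstruction:
    """Read a three-file sparse text model from a directory.

    Raises :class:`FormatError` if a file is missing or malformed and
    :class:`IntegrityError` if observation/track cross-links are broken.
    """
    path = Path(path)
    for fname in ("cameras.txt", "images.txt", "points3D.txt"):
        if not (path / fname).exists():
            raise FormatError(f"missing sparse-model file: {path / fname}")

    recon = SparseReconstruction()

    for line in _data_lines(path / "cameras.txt"):
        tok = line.split()
        if len(tok) < 4:
            raise FormatError(f"malformed camera record: {line!r}")
        cam = CameraIntrinsics(
            camera_id=int(tok[0]),
            model_name=tok[1],
            width=int(tok[2]),
            height=int(tok[3]),
            params=np.array([float(x) for x in tok[4:]]),
        )
        recon.cameras[cam.camera_id] = cam

    lines = list(_data_lines(path / "images.txt"))
    if len(lines) % 2 != 0:
        raise FormatError("images.txt must contain two lines per registered frame")
    for head, obs in zip(lines[0::2], lines[1::2]):
        tok = head.split()
        if len(tok) < 10:
            raise FormatError(f"malformed image header: {head!r}")
        ot = obs.split()
        if len(ot) % 3 != 0:
            raise FormatError("observation line length must be a multiple of 3")
        xys = np.array([[float(ot[i]), float(ot[i + 1])] for i in range(0, len(ot), 3)])
        pids = np.array([int(ot[i + 2]) for i in range(0, len(ot), 3)], dtype=np.int64)
        frame = FramePose(
            frame_id=int(tok[0]),
            qvec=np.array([float(x) for x in tok[1:5]]),
            tvec=np.array([float(x) for x in tok[5:8]]),
            camera_id=int(tok[8]),
            name=tok[9],
            xys=xys.reshape(-1, 2),
            point3d_ids=pids,
        )
        recon.frames[frame.frame_id] = frame

    for line in _data_lines(path / "points3D.txt"):
        tok = line.split()
        if len(tok) < 8 or (len(tok) - 8) % 2 != 0:
            raise FormatError(f"malformed point record: {line!r}")
        track = [(int(tok[i]), int(tok[i + 1])) for i in range(8, len(tok), 2)]
        pt = Point3D(
            point_id=int(tok[0]),
            xyz=np.array([float(x) for x in tok[1:4]]),
            color=np.array([int(x) for x in tok[4:7]], dtype=np.uint8),
            reproj_error=float(tok[7]),
            track=track,
        )
        recon.points[pt.point_id] = pt

    recon.validate()
    return recon


def _data_lines(fname: Path):
    with open(fname) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                yield line


def write_colmap_sparse(recon: SparseReconstruction, path: str | Path) -> None:
    """Write the three-file sparse text model; inverse of :func:`read_colmap_sparse`.

    Reals are emitted with 17 significant digits so the round trip is exact to
    double precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "cameras.txt", "w") as fh:
        fh.write("# Camera list with one line of data per camera:\n")
        fh.write("#   CAMERA_ID, MODEL, WIDTH, HEIGHT, PARAMS[]\n")
        fh.write(f"# Number of cameras: {len(recon.cameras)}\n")
        for cid in sorted(recon.cameras):
            cam = recon.cameras[cid]
            params = " ".join(_fmt(p) for p in cam.params)
            fh.write(f"{cid} {cam.model_name} {cam.width} {cam.height} {params}\n")

    with open(path / "images.txt", "w") as fh:
        fh.write("# Image list with two lines of data per image:\n")
        fh.write("#   IMAGE_ID, QW, QX, QY, QZ, TX, TY, TZ, CAMERA_ID, NAME\n")
        fh.write("#   POINTS2D[] as (X, Y, POINT3D_ID)\n")
        fh.write(f"# Number of images: {len(recon.frames)}\n")
        for fid in sorted(recon.frames):
            fr = recon.frames[fid]
            q = " ".join(_fmt(x) for x in fr.qvec)
            t = " ".join(_fmt(x) for x in fr.tvec)
            name = fr.name or f"frame{fid:06d}.png"
            fh.write(f"{fid} {q} {t} {fr.camera_id} {name}\n")
            obs = " ".join(
                f"{_fmt(x)} {_fmt(y)} {int(pid)}"
                for (x, y), pid in zip(fr.xys, fr.point3d_ids)
            )
            fh.write(obs + "\n")

    with open(path / "points3D.txt", "w") as fh:
        fh.write("# 3D point list with one line of data per point:\n")
        fh.write("#   POINT3D_ID, X, Y, Z, R, G, B, ERROR, TRACK[] as (IMAGE_ID, POINT2D_IDX)\n")
        fh.write(f"# Number of points: {len(recon.points)}\n")
        for pid in sorted(recon.points):
            pt = recon.points[pid]
            xyz = " ".join(_fmt(x) for x in pt.xyz)
            rgb = " ".join(str(int(c)) for c in pt.color)
            track = " ".join(f"{f} {o}" for f, o in pt.track)
            fh.write(f"{pid} {xyz} {rgb} {_fmt(pt.reproj_error)} {track}".rstrip() + "\n")


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_ply_header(fh) -> tuple[str, list[tuple[str, int, list]]]:
    """Parse a PLY header; returns (format, [(element, count, properties)]).

    Properties are (name, dtype_code) or ("list", count_code, item_code, name).
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise FormatError("not a PLY file (missing magic)")
    fmt = None
    elements: list[tuple[str, int, list]] = []
    while True:
        raw = fh.readline()
        if not raw:
            raise FormatError("unterminated PLY header")
        tok = raw.decode("ascii").strip().split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise FormatError("property before element in PLY header")
            if tok[1] == "list":
                elements[-1][2].append(("list", _PLY_TYPES[tok[2]], _PLY_TYPES[tok[3]], tok[4]))
            else:
                elements[-1][2].append((tok[2], _PLY_TYPES[tok[1]]))
        elif tok[0] == "end_header":
            break
        else:
            raise FormatError(f"unexpected PLY header line: {tok}")
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"unsupported PLY format {fmt!r}")
    return fmt, elements


def _read_ply(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Read vertex/face elements of an ascii or binary-little-endian PLY."""
    out: dict[str, dict[str, np.ndarray]] = {}
    with open(path, "rb") as fh:
        fmt, elements = _parse_ply_header(fh)
        for name, count, props in elements:
            has_list = any(p[0] == "list" for p in props)
            if not has_list:
                dtype = np.dtype([(p[0], "<" + p[1]) for p in props])
                if fmt == "binary_little_endian":
                    data = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype, count=count)
                else:
                    rows = [fh.readline().split() for _ in range(count)]
                    data = np.array([tuple(r) for r in rows], dtype=dtype)
                out[name] = {p[0]: np.ascontiguousarray(data[p[0]]) for p in props}
            else:
                if len(props) != 1:
                    raise FormatError("mixed list/scalar properties are not supported")
                _, cnt_t, item_t, pname = props[0]
                rows = []
                if fmt == "binary_little_endian":
                    cnt_dt = np.dtype("<" + cnt_t)
                    item_dt = np.dtype("<" + item_t)
                    for _ in range(count):
                        k = int(np.frombuffer(fh.read(cnt_dt.itemsize), dtype=cnt_dt)[0])
                        rows.append(np.frombuffer(fh.read(item_dt.itemsize * k), dtype=item_dt, count=k))
                else:
                    for _ in range(count):
                        tok = fh.readline().split()
                        k = int(tok[0])
                        rows.append(np.array(tok[1 : 1 + k], dtype=item_t))
                out[name] = {pname: rows}
    return out


def read_ply_points(path: str | Path) -> dict[str, np.ndarray]:
    """Read a PLY vertex element (ascii or binary little-endian).

    Returns a dict with ``points`` (N, 3) float64 and, when present,
    ``normals`` (N, 3), ``colors`` (N, 3) uint8 and ``labels`` (N,) int.
    """
    data = _read_ply(path)
    if "vertex" not in data:
        raise FormatError("PLY file has no vertex element")
    v = data["vertex"]
    for ax in ("x", "y", "z"):
        if ax not in v:
            raise FormatError(f"vertex element lacks coordinate {ax!r}")
    out = {"points": np.stack([v["x"], v["y"], v["z"]], axis=1).astype(np.float64)}
    if all(k in v for k in ("nx", "ny", "nz")):
        out["normals"] = np.stack([v["nx"], v["ny"], v["nz"]], axis=1).astype(np.float64)
    if all(k in v for k in ("red", "green", "blue")):
        out["colors"] = np.stack([v["red"], v["green"], v["blue"]], axis=1).astype(np.uint8)
    if "label" in v:
        out["labels"] = v["label"].astype(np.int64)
    return out


def write_ply_points(
    path: str | Path,
    points: np.ndarray,
    normals: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    binary: bool = True,
) -> None:
    """Write a point cloud as PLY (binary little-endian by default).

    Coordinates and normals are stored as float64 so write→read is bitwise
    exact in the binary dialect.
    """
    points = np.asarray(points, dtype="<f8").reshape(-1, 3)
    n = len(points)
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    cols = [points[:, 0], points[:, 1], points[:, 2]]
    if normals is not None:
        normals = np.asarray(normals, dtype="<f8").reshape(n, 3)
        fields += [("nx", "<f8"), ("ny", "<f8"), ("nz", "<f8")]
        cols += [normals[:, 0], normals[:, 1], normals[:, 2]]
    if colors is not None:
        colors = np.asarray(colors, dtype="u1").reshape(n, 3)
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        cols += [colors[:, 0], colors[:, 1], colors[:, 2]]
    if labels is not None:
        labels = np.asarray(labels, dtype="<i4").reshape(n)
        fields += [("label", "<i4")]
        cols += [labels]
    rec = np.empty(n, dtype=np.dtype(fields))
    for (name, _), col in zip(fields, cols):
        rec[name] = col

    ply_type = {"<f8": "double", "u1": "uchar", "<i4": "int"}
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += [f"property {ply_type[t]} {name}" for name, t in fields]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for row in rec:
                fh.write((" ".join(_fmt(x) if isinstance(x, float) else str(x) for x in row) + "\n").encode("ascii"))


def read_ply_mesh(path: str | Path) -> TriangleMesh:
    """Read a triangle mesh PLY (ascii or binary little-endian)."""
    data = _read_ply(path)
    if "vertex" not in data or "face" not in data:
        raise FormatError("mesh PLY requires vertex and face elements")
    v = data["vertex"]
    verts = np.stack([v["x"], v["y"], v["z"]], axis=1).astype(np.float64)
    face_prop = next(iter(data["face"].values()))
    faces = np.array([np.asarray(f)[:3] for f in face_prop], dtype=np.int64)
    normals = None
    if all(k in v for k in ("nx", "ny", "nz")):
        normals = np.stack([v["nx"], v["ny"], v["nz"]], axis=1).astype(np.float64)
    colors = None
    if all(k in v for k in ("red", "green", "blue")):
        colors = np.stack([v["red"], v["green"], v["blue"]], axis=1).astype(np.uint8)
    return TriangleMesh(verts, faces, vertex_normals=normals, vertex_colors=colors)


def write_ply_mesh(path: str | Path, mesh: TriangleMesh, binary: bool = True) -> None:
    """Write a triangle mesh as PLY with optional per-vertex normals/colors."""
    n = len(mesh.vertices)
    fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
    cols = [mesh.vertices[:, i] for i in range(3)]
    if mesh.vertex_normals is not None:
        fields += [("nx", "<f8"), ("ny", "<f8"), ("nz", "<f8")]
        cols += [mesh.vertex_normals[:, i] for i in range(3)]
    if mesh.vertex_colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        cols += [mesh.vertex_colors[:, i] for i in range(3)]
    rec = np.empty(n, dtype=np.dtype(fields))
    for (name, _), col in zip(fields, cols):
        rec[name] = col
    ply_type = {"<f8": "double", "u1": "uchar"}
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += [f"property {ply_type[t]} {name}" for name, t in fields]
    header.append(f"element face {len(mesh.faces)}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
            for f in mesh.faces:
                fh.write(struct.pack("<B3i", 3, *[int(i) for i in f]))
        else:
            for row in rec:
                fh.write((" ".join(_fmt(x) if isinstance(x, float) else str(x) for x in row) + "\n").encode("ascii"))
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


# ---------------------------------------------------------------------------
# Frame directories
# ---------------------------------------------------------------------------


def read_frame_dir(path: str | Path, pattern: str = "*.png", channel: str = "RGB") -> FrameSequence:
    """Load an image-frame directory (lexicographic order) as a FrameSequence.

    All frames must share dimensions; offenders are listed in the error.
    """
    import imageio.v3 as iio

    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"frame directory does not exist: {path}")
    files = sorted(path.glob(pattern))
    frames, names = [], []
    for f in files:
        img = np.asarray(iio.imread(f))
        if channel == "RGB" and img.ndim == 3 and img.shape[2] == 4:
            img = img[..., :3]
        if channel != "RGB" and img.ndim == 3:
            img = img[..., "RGB".index(channel) if channel in "RGB" else 0]
        frames.append(img)
        names.append(f.name)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        offenders = [n for n, f in zip(names, frames) if f.shape != frames[0].shape]
        raise ValueError(f"mixed frame dimensions {sorted(shapes)}; offenders: {offenders}")
    return FrameSequence(frames=frames, channel=channel, source_id=str(path), names=names)
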