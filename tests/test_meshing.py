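import numpy as np
import pytest

from gastro3d import meshing
from gastro3d.io_formats import (
    CameraIntrinsics,
    FramePose,
    SparseReconstruction,
    TriangleMesh,
    rotmat_to_quat,
)
from gastro3d.frame_preprocess import FrameSequence


def _single_camera_recon(center, look_at):
    from gastro3d.synthetic_data import _look_at_rotation

    R = _look_at_rotation(np.asarray(center, float), np.asarray(look_at, float))
    recon = SparseReconstruction()
    recon.cameras[1] = CameraIntrinsics(1, "PINHOLE", 100, 100, [50.0, 50.0, 50.0, 50.0])
    recon.frames[1] = FramePose(
        frame_id=1,
        qvec=rotmat_to_quat(R),
        tvec=-R @ np.asarray(center, float),
        camera_id=1,
    )
    return recon


class TestEstimateNormals:
    def test_planar_cloud_gives_z_normals(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (200, 2)), np.zeros(200)])
        nf = meshing.estimate_normals(pts, k=20)
        assert np.abs(np.abs(nf.normals[:, 2]) - 1).max() < 1e-9
        assert not nf.oriented

    def test_sphere_normals_radial_within_5_degrees(self, sphere_cloud):
        nf = meshing.estimate_normals(sphere_cloud, k=100)
        cos = np.abs(np.einsum("ij,ij->i", nf.normals, sphere_cloud))
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert (ang <= 5).mean() >= 0.99

    def test_three_points_give_their_plane_normal(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        nf = meshing.estimate_normals(pts, k=100)  # k clamps to N-1
        assert np.abs(np.abs(nf.normals[:, 2]) - 1).max() < 1e-9

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            meshing.estimate_normals(np.zeros((2, 3)))

    def test_all_normals_unit_length(self, rng):
        pts = rng.normal(size=(500, 3))
        nf = meshing.estimate_normals(pts, k=30)
        np.testing.assert_allclose(np.linalg.norm(nf.normals, axis=1), 1.0, atol=1e-9)


class TestOrientNormals:
    def test_flip_toward_single_camera(self):
        recon = _single_camera_recon([0, 0, 0], [0, 0, 1])
        pts = np.array([[0.0, 0, 1]])
        nf = meshing.orient_normals(pts, np.array([[0.0, 0, 1]]), recon)
        np.testing.assert_allclose(nf.normals, [[0, 0, -1]], atol=1e-12)
        assert nf.oriented

    def test_orthogonal_normal_kept_unflipped(self):
        recon = _single_camera_recon([0, 0, 0], [0, 0, 1])
        pts = np.array([[0.0, 0, 1]])
        nf = meshing.orient_normals(pts, np.array([[1.0, 0, 0]]), recon)
        np.testing.assert_allclose(nf.normals, [[1, 0, 0]], atol=1e-12)

    def test_sphere_with_interior_cameras_points_inward(self, small_scene):
        pts = small_scene.points[small_scene.inlier_mask]
        nf = meshing.estimate_normals(pts, k=60)
        stage_like = type("S", (), {"points": pts, "ids": None})()
        oriented = meshing.orient_normals(pts, nf, small_scene.recon)
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        inward = np.einsum("ij,ij->i", oriented.normals, -dirs)
        assert (inward > 0).mean() >= 0.99

    def test_no_registered_frames_raises(self):
        with pytest.raises(ValueError):
            meshing.orient_normals(np.zeros((1, 3)), np.array([[0.0, 0, 1]]), SparseReconstruction())


class TestSmoothNormals:
    def test_uniform_field_is_fixed_point(self, rng):
        pts = rng.normal(size=(50, 3))
        nrm = np.tile([0.0, 0.0, 1.0], (50, 1))
        out = meshing.smooth_normals(pts, nrm, k_smooth=10)
        np.testing.assert_allclose(out.normals, nrm, atol=1e-12)

    def test_single_flipped_normal_restored(self, rng):
        pts = rng.normal(size=(51, 3)) * 0.1
        nrm = np.tile([0.0, 0.0, 1.0], (51, 1))
        nrm[0] = [0, 0, -1.0]
        out = meshing.smooth_normals(pts, nrm, k_smooth=30)
        assert out.normals[0, 2] > 0

    def test_k_one_is_identity(self, rng):
        pts = rng.normal(size=(20, 3))
        nrm = rng.normal(size=(20, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        out = meshing.smooth_normals(pts, nrm, k_smooth=1)
        np.testing.assert_array_equal(out.normals, nrm)


class TestReconstructSurface:
    def test_sphere_rms_within_2_percent_at_depth6(self, sphere_cloud):
        normals = meshing.orient_toward_point(sphere_cloud, sphere_cloud.copy(), np.zeros(3))
        mesh = meshing.reconstruct_surface(sphere_cloud, normals, depth=6)
        radii = np.linalg.norm(mesh.vertices, axis=1)
        rms = np.sqrt(np.mean((radii - 1.0) ** 2))
        assert rms <= 0.02

    def test_vertex_count_increases_with_depth(self, sphere_cloud):
        normals = meshing.orient_toward_point(sphere_cloud, sphere_cloud.copy(), np.zeros(3))
        counts = [
            len(meshing.reconstruct_surface(sphere_cloud, normals, depth=d).vertices)
            for d in (4, 5, 6)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            meshing.reconstruct_surface(np.zeros((0, 3)), np.zeros((0, 3)), depth=4)

    def test_coincident_points_raise(self):
        pts = np.zeros((10, 3))
        nrm = np.tile([0.0, 0, 1], (10, 1))
        with pytest.raises(ValueError):
            meshing.reconstruct_surface(pts, nrm, depth=4)


class TestCameraScoring:
    def _face_mesh(self):
        # one triangle in the z=0 plane, normal +z
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        return TriangleMesh(verts, np.array([[0, 1, 2]]))

    def test_face_on_camera_beats_oblique(self):
        mesh = self._face_mesh()
        centroid = mesh.face_centroids()[0]
        d = 2.0
        recon = SparseReconstruction()
        recon.cameras[1] = CameraIntrinsics(1, "PINHOLE", 100, 100, [50.0, 50.0, 50.0, 50.0])
        from gastro3d.synthetic_data import _look_at_rotation

        # camera A face-on above the centroid; camera B at 60 degrees, same distance
        for fid, center in ((1, centroid + [0, 0, d]),
                            (2, centroid + [d * np.sin(np.pi / 3), 0, d * np.cos(np.pi / 3)])):
            R = _look_at_rotation(np.asarray(center), centroid)
            recon.frames[fid] = FramePose(
                frame_id=fid, qvec=rotmat_to_quat(R), tvec=-R @ np.asarray(center), camera_id=1
            )
        scores = meshing.score_cameras_for_face(0, mesh, recon)
        assert [s.frame_id for s in scores] == [1, 2]
        assert scores[0].angle_cos == pytest.approx(1.0, abs=1e-9)
        assert scores[1].angle_cos == pytest.approx(0.5, abs=1e-9)

    def test_nearer_of_two_face_on_cameras_ranks_first(self):
        mesh = self._face_mesh()
        centroid = mesh.face_centroids()[0]
        recon = SparseReconstruction()
        recon.cameras[1] = CameraIntrinsics(1, "PINHOLE", 100, 100, [50.0, 50.0, 50.0, 50.0])
        from gastro3d.synthetic_data import _look_at_rotation

        for fid, d in ((1, 1.0), (2, 2.0)):
            center = centroid + [0, 0, d]
            R = _look_at_rotation(center, centroid)
            recon.frames[fid] = FramePose(
                frame_id=fid, qvec=rotmat_to_quat(R), tvec=-R @ center, camera_id=1
            )
        scores = meshing.score_cameras_for_face(0, mesh, recon)
        assert [s.frame_id for s in scores] == [1, 2]

    def test_camera_behind_face_excluded(self):
        mesh = self._face_mesh()
        centroid = mesh.face_centroids()[0]
        recon = _single_camera_recon(centroid + [0, 0, -2.0], centroid)
        assert meshing.score_cameras_for_face(0, mesh, recon) == []


class TestColorTransfer:
    def test_uniform_red_images_give_red_vertices(self, small_scene):
        import gastro3d as g

        pts = small_scene.points[small_scene.inlier_mask]
        nf = meshing.estimate_normals(pts, k=60)
        normals = meshing.orient_toward_point(pts, nf.normals, np.zeros(3))
        mesh = meshing.reconstruct_surface(pts, normals, depth=5)
        fids = sorted(small_scene.recon.frames)
        frames = FrameSequence(
            frames=[np.full((256, 256, 3), (255, 0, 0), dtype=np.uint8) for _ in fids],
            channel="RGB",
            indices=fids,
        )
        out = meshing.transfer_vertex_colors(mesh, small_scene.recon, frames)
        colored = ~(out.vertex_colors == meshing.SENTINEL_GRAY).all(axis=1)
        assert colored.mean() > 0.9
        assert (out.vertex_colors[colored] == (255, 0, 0)).all()

    def test_vertex_with_no_camera_gets_sentinel_gray(self):
        # camera looks at +z; a vertex far behind it can never project inside
        recon = _single_camera_recon([0, 0, 0], [0, 0, 1])
        # the whole face sits behind the camera and can never project inside
        mesh = TriangleMesh(
            np.array([[0.0, 0, -5], [1, 0, -5], [0, 1, -5]]), np.array([[0, 1, 2]])
        )
        frames = FrameSequence(
            frames=[np.full((100, 100, 3), 9, dtype=np.uint8)], channel="RGB", indices=[1]
        )
        out = meshing.transfer_vertex_colors(mesh, recon, frames)
        assert (out.vertex_colors == meshing.SENTINEL_GRAY).all()

    def test_missing_image_for_registered_frame_raises(self):
        recon = _single_camera_recon([0, 0, 0], [0, 0, 1])
        mesh = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        frames = FrameSequence(frames=[], channel="RGB", indices=[])
        with pytest.raises(FileNotFoundError):
            meshing.transfer_vertex_colors(mesh, recon, frames)

    def test_per_camera_colors_match_best_ranked_camera(self, small_scene):
        """Cross-check color transfer against the face-level camera ranking."""
        pts = small_scene.points[small_scene.inlier_mask]
        nf = meshing.estimate_normals(pts, k=60)
        normals = meshing.orient_toward_point(pts, nf.normals, np.zeros(3))
        mesh = meshing.reconstruct_surface(pts, normals, depth=4)
        fids = sorted(small_scene.recon.frames)
        palette = {fid: (10 + 3 * i, 20, 200 - 3 * i) for i, fid in enumerate(fids)}
        frames = FrameSequence(
            frames=[np.full((256, 256, 3), palette[f], dtype=np.uint8) for f in fids],
            channel="RGB",
            indices=fids,
        )
        out = meshing.transfer_vertex_colors(mesh, small_scene.recon, frames)
        color_to_fid = {tuple(v): k for k, v in palette.items()}
        # spot-check: for faces whose three vertices agree on a source camera,
        # that camera must also win the face-level ranking
        vnorm = mesh.compute_vertex_normals()
        checked = 0
        for fi in range(0, len(mesh.faces), max(1, len(mesh.faces) // 40)):
            cols = [tuple(out.vertex_colors[v]) for v in mesh.faces[fi]]
            if len(set(cols)) != 1 or cols[0] not in color_to_fid:
                continue
            scores = meshing.score_cameras_for_face(fi, mesh, small_scene.recon)
            if not scores:
                continue
            checked += 1
            assert color_to_fid[cols[0]] in [s.frame_id for s in scores[:3]]
        assert checked >= 5
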