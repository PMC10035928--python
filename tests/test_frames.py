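"""Anatomical frames, rigid alignment, patch centroids, projection, file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from spinetopo.frames import (
    AnatomicalFrame,
    GeometryError,
    SurfacePatch,
    align_scan_to_mri,
    build_frame,
    patch_centroid,
    project_to_plane,
    read_demographics,
    read_landmarks,
    read_patch,
    write_demographics,
    write_landmarks,
)
from spinetopo.synthetic import LandmarkSet, generate_cohort


def random_rotation(seed):
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


class TestBuildFrame:
    def test_axis_aligned_case(self):
        f = build_frame((0, 0, 400), (0, 0, 0), (0, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(f.origin, [0, 0, 400])
        np.testing.assert_allclose(f.rotation, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotated_inputs_rotate_axes(self, seed):
        R = random_rotation(seed)
        l1, pl, pr = np.array([5.0, 2.0, 400.0]), np.array([40.0, 0, 0]), np.array([-40.0, 0, 0])
        normal = np.array([0.0, 1.0, 0.0])
        f0 = build_frame(l1, pl, pr, normal)
        f1 = build_frame(R @ l1, R @ pl, R @ pr, R @ normal)
        np.testing.assert_allclose(f1.rotation, R @ f0.rotation, atol=1e-9)
        np.testing.assert_allclose(f1.origin, R @ l1, atol=1e-9)

    def test_coincident_inputs_rejected(self):
        with pytest.raises(GeometryError):
            build_frame((0, 0, 0), (40, 0, 0), (-40, 0, 0), (0, 1, 0))

    def test_line_parallel_to_normal_rejected(self):
        with pytest.raises(GeometryError):
            build_frame((0, 400, 0), (0, 0, 0), (0, 0, 0), (0, 1, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_axes_orthonormal_right_handed_for_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        l1 = rng.uniform(-100, 100, 3) + np.array([0, 0, 400.0])
        pl = rng.uniform(-100, 100, 3)
        pr = rng.uniform(-100, 100, 3)
        n = rng.normal(size=3)
        line = l1 - (pl + pr) / 2
        if (np.linalg.norm(line) < 1.0 or np.linalg.norm(n) < 1e-6
                or np.linalg.norm(np.cross(line, n)) < 1.0):
            return
        f = build_frame(l1, pl, pr, n)
        R = f.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def _landmark_set(coords, source="SCAN_MARKER", labels=None, **kw):
    n = len(coords)
    if labels is None:
        labels = [f"T{i + 1}" for i in range(n)]
    return LandmarkSet(subject_id="S001", source=source, labels=labels,
                       coords=np.asarray(coords, float), **kw)


def _chain(n=6, seed=0):
    rng = np.random.default_rng(seed)
    z = np.linspace(400, 100, n)
    return np.column_stack([rng.normal(0, 5, n), rng.normal(0, 5, n), z])


class TestAlignment:
    def test_identity_for_coincident_sets(self):
        c = _chain()
        mri = _landmark_set(c, source="MRI_FIDUCIAL")
        scan = _landmark_set(c)
        tf, aligned = align_scan_to_mri(scan, mri)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-9)
        assert tf.residual_rms < 1e-9
        np.testing.assert_allclose(aligned.coords, mri.coords, atol=1e-9)

    def test_pure_translation_recovered(self):
        c = _chain()
        mri = _landmark_set(c, source="MRI_FIDUCIAL")
        scan = _landmark_set(c + np.array([3.0, -2.0, 7.0]))
        tf, _ = align_scan_to_mri(scan, mri)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(tf.translation, [-3.0, 2.0, -7.0], atol=1e-9)
        assert tf.residual_rms < 1e-9

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_random_rigid_motion_round_trip(self, seed):
        c = _chain(seed=seed)
        R = random_rotation(seed)
        t = np.random.default_rng(seed).uniform(-50, 50, 3)
        mri = _landmark_set(c, source="MRI_FIDUCIAL")
        scan = _landmark_set(c @ R.T + t, frame="scan")
        tf, aligned = align_scan_to_mri(scan, mri)
        assert tf.residual_rms < 1e-9
        np.testing.assert_allclose(aligned.coords, mri.coords, atol=1e-8)
        np.testing.assert_allclose(tf.rotation @ R, np.eye(3), atol=1e-9)

    def test_residual_invariant_to_common_rigid_motion(self):
        rng = np.random.default_rng(6)
        c = _chain(seed=6)
        noisy = c + rng.normal(0, 1.0, c.shape)
        r0 = align_scan_to_mri(
            _landmark_set(noisy), _landmark_set(c, source="MRI_FIDUCIAL")
        )[0].residual_rms
        R, t = random_rotation(7), np.array([10.0, -4.0, 2.0])
        r1 = align_scan_to_mri(
            _landmark_set(noisy @ R.T + t, frame="scan"),
            _landmark_set(c @ R.T + t, source="MRI_FIDUCIAL", frame="scan"),
        )[0].residual_rms
        assert r0 == pytest.approx(r1, abs=1e-9)

    def test_too_few_shared_labels_rejected(self):
        mri = _landmark_set(_chain(2), source="MRI_FIDUCIAL", labels=["T1", "T2"])
        scan = _landmark_set(_chain(2), labels=["T1", "T2"])
        with pytest.raises(ValueError, match="shared labels"):
            align_scan_to_mri(scan, mri)

    def test_collinear_labels_warn_and_stay_rigid(self):
        z = np.linspace(400, 100, 5)
        c = np.column_stack([np.zeros(5), np.zeros(5), z])
        mri = _landmark_set(c, source="MRI_FIDUCIAL")
        scan = _landmark_set(c + np.array([2.0, 1.0, 0.0]))
        with pytest.warns(UserWarning, match="collinear"):
            tf, aligned = align_scan_to_mri(scan, mri)
        assert tf.residual_rms < 1e-6
        np.testing.assert_allclose(aligned.coords, mri.coords, atol=1e-6)


class TestPatchCentroid:
    def test_single_triangle_both_modes(self):
        patch = SurfacePatch([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 2)])
        for mode in ("vertex_mean", "area_weighted"):
            np.testing.assert_allclose(
                patch_centroid(patch, mode), [1 / 3, 1 / 3, 0], atol=1e-12
            )

    def test_unit_square_two_triangles(self):
        patch = SurfacePatch(
            [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], [(0, 1, 2), (0, 2, 3)]
        )
        np.testing.assert_allclose(
            patch_centroid(patch, "area_weighted"), [0.5, 0.5, 0], atol=1e-12
        )

    def test_skewed_mesh_matches_monte_carlo_surface_integral(self, rng):
        verts = np.array(
            [(0, 0, 0), (10, 0, 0), (0, 10, 0), (10.2, 0.1, 0.0)], dtype=float
        )
        tris = np.array([(0, 1, 2), (1, 3, 2)])
        # uniform sampling over the two faces, area-proportional
        tri_pts = verts[tris]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0]), axis=1
        )
        n = 200_000
        counts = rng.multinomial(n, areas / areas.sum())
        samples = []
        for (a, b, c), m in zip(tri_pts, counts):
            u, v = rng.random(m), rng.random(m)
            flip = u + v > 1
            u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
            samples.append(a + u[:, None] * (b - a) + v[:, None] * (c - a))
        mc = np.vstack(samples).mean(axis=0)
        got = patch_centroid(SurfacePatch(verts, tris), "area_weighted")
        np.testing.assert_allclose(got, mc, atol=1e-1 * np.sqrt(areas.sum()) / np.sqrt(n) * 100 + 1e-3)

    def test_vertex_mean_permutation_and_translation(self, rng):
        verts = rng.normal(size=(8, 3))
        patch = SurfacePatch(verts, np.empty((0, 3), dtype=int))
        perm = rng.permutation(8)
        np.testing.assert_allclose(
            patch_centroid(patch, "vertex_mean"),
            patch_centroid(SurfacePatch(verts[perm], np.empty((0, 3), int)), "vertex_mean"),
            atol=1e-12,
        )
        shifted = SurfacePatch(verts + [1, 2, 3], np.empty((0, 3), int))
        np.testing.assert_allclose(
            patch_centroid(shifted, "vertex_mean"),
            patch_centroid(patch, "vertex_mean") + [1, 2, 3],
            atol=1e-12,
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SurfacePatch(np.empty((0, 3)), np.empty((0, 3), int))
        flat = SurfacePatch([(0, 0, 0), (1, 0, 0), (2, 0, 0)], [(0, 1, 2)])
        with pytest.raises(GeometryError, match="area"):
            patch_centroid(flat, "area_weighted")

    def test_read_patch_ascii(self, tmp_path):
        path = tmp_path / "patch.txt"
        path.write_text("# marker patch\nv 0 0 0\nv 1 0 0\nv 0 1 0\nf 0 1 2\n")
        patch = read_patch(path)
        np.testing.assert_allclose(
            patch_centroid(patch, "area_weighted"), [1 / 3, 1 / 3, 0], atol=1e-12
        )


class TestProjection:
    def test_identity_frame_reads_off_coordinates(self):
        c = _chain(seed=1)
        s = _landmark_set(c)
        f = AnatomicalFrame.identity()
        sag = project_to_plane(s, f, "sagittal")
        cor = project_to_plane(s, f, "coronal")
        np.testing.assert_allclose(sag.z, c[:, 2])
        np.testing.assert_allclose(sag.v, c[:, 1])
        np.testing.assert_allclose(cor.v, c[:, 0])

    def test_translated_frame_shifts_pairs(self):
        c = _chain(seed=2)
        s = _landmark_set(c)
        t = np.array([4.0, -3.0, 12.0])
        sag0 = project_to_plane(s, AnatomicalFrame.identity(), "sagittal")
        sag1 = project_to_plane(s, AnatomicalFrame.identity(origin=t), "sagittal")
        np.testing.assert_allclose(sag1.z, sag0.z - t[2], atol=1e-12)
        np.testing.assert_allclose(sag1.v, sag0.v - t[1], atol=1e-12)

    @pytest.mark.parametrize("plane", ["sagittal", "coronal"])
    def test_rotated_frame_round_trip(self, plane):
        c = _chain(seed=3)
        R = random_rotation(9)
        f0 = AnatomicalFrame.identity()
        f1 = AnatomicalFrame(
            origin=np.zeros(3),
            axis_lateral=R[:, 0],
            axis_anteroposterior=R[:, 1],
            axis_cephalocaudal=R[:, 2],
        )
        # projecting rotated points in the rotated frame == identity case
        rot_set = _landmark_set(c @ R.T, frame="scan")
        p0 = project_to_plane(_landmark_set(c), f0, plane)
        p1 = project_to_plane(rot_set, f1, plane)
        np.testing.assert_allclose(p1.z, p0.z, atol=1e-9)
        np.testing.assert_allclose(p1.v, p0.v, atol=1e-9)


class TestCSVRoundTrip:
    def test_cohort_round_trip_lossless(self, tmp_path, default_cohort):
        _, demographics, sets = default_cohort
        lpath, dpath = tmp_path / "lm.csv", tmp_path / "demo.csv"
        write_landmarks(sets, lpath)
        write_demographics(demographics, dpath)
        sets2 = read_landmarks(lpath)
        demo2 = read_demographics(dpath)
        by_key = {(s.subject_id, s.source, s.session): s for s in sets2}
        assert len(sets2) == len(sets)
        for s in sets:
            r = by_key[(s.subject_id, s.source, s.session)]
            assert r.labels == s.labels
            np.testing.assert_allclose(r.coords, s.coords, atol=1e-9)
        assert [d.subject_id for d in demo2] == [d.subject_id for d in demographics]
        for a, b in zip(demographics, demo2):
            assert b.height_m == pytest.approx(a.height_m, abs=1e-9)
            assert b.weight_kg == pytest.approx(a.weight_kg, abs=1e-9)

    def test_unknown_label_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,source,session,label,x_mm,y_mm,z_mm\n"
            "S001,MRI_SPINOUS,1,T1,0,0,400\n"
            "S001,MRI_SPINOUS,1,T13,0,0,100\n"
        )
        with pytest.raises(ValueError, match="T13.*row 3"):
            read_landmarks(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,source,label,x_mm,y_mm,z_mm\nS001,MRI_SPINOUS,T1,0,0,400\n")
        with pytest.raises(ValueError, match="session"):
            read_landmarks(path)

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject_id,source,session,label,x_mm,y_mm,z_mm\n"
            "S001,MRI_SPINOUS,1,T1,0,0,400\n"
            "S001,MRI_SPINOUS,1,T1,1,0,390\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_landmarks(path)
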