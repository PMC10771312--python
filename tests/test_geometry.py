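"""Rigid-transform, plane-classification and cropping primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from owhto.geometry import (
    Axis3D,
    Plane,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    classify_by_plane,
    crop_mesh,
    mirror_mesh,
    rotation_about_axis,
)

Z_AXIS = Axis3D.through([0, 0, 0], [0, 0, 1], "z")


class TestRotationAboutAxis:
    def test_zero_angle_is_identity(self):
        T = rotation_about_axis(Z_AXIS, 0.0)
        assert T.is_identity(tol=1e-12)

    def test_quarter_turn_about_z(self):
        T = rotation_about_axis(Z_AXIS, 90.0)
        np.testing.assert_allclose(T.apply([1.0, 0.0, 0.0]), [0, 1, 0], atol=1e-12)

    def test_rodrigues_closed_form_about_y(self):
        # independent closed form: R_y(30) @ (10,0,0) = (10 cos30, 0, -10 sin30)
        axis = Axis3D.through([0, 0, 0], [0, 1, 0], "y")
        got = rotation_about_axis(axis, 30.0).apply([10.0, 0.0, 0.0])
        np.testing.assert_allclose(got, [8.66025403784, 0.0, -5.0], atol=1e-9)

    def test_off_origin_axis_fixes_axis_points(self):
        axis = Axis3D.through([5.0, -2.0, 3.0], [0.3, -0.5, 0.8], "a")
        T = rotation_about_axis(axis, 37.0)
        np.testing.assert_allclose(T.apply(axis.point), axis.point, atol=1e-12)
        on_axis = axis.point + 7.3 * axis.direction
        np.testing.assert_allclose(T.apply(on_axis), on_axis, atol=1e-12)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            Axis3D([0, 0, 0], [0, 0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        theta=st.floats(-180, 180),
        seed=st.integers(0, 2**16),
    )
    def test_inverse_angle_composes_to_identity(self, theta, seed):
        rng = np.random.default_rng(seed)
        axis = Axis3D.through(rng.normal(size=3), rng.normal(size=3) + 1e-3, "r")
        T = rotation_about_axis(axis, theta).compose(rotation_about_axis(axis, -theta))
        pts = rng.normal(size=(5, 3))
        np.testing.assert_allclose(T.apply(pts), pts, atol=1e-9)


class TestApplyTransform:
    def test_identity_returns_identical_mesh(self, unit_cube):
        out = apply_transform(unit_cube, RigidTransform.identity())
        assert np.array_equal(out.vertices, unit_cube.vertices)
        assert np.array_equal(out.faces, unit_cube.faces)

    def test_pure_translation(self, unit_cube):
        T = RigidTransform(np.eye(3), [0.0, 0.0, 5.0])
        out = apply_transform(unit_cube, T)
        np.testing.assert_array_equal(out.vertices[:, 2], unit_cube.vertices[:, 2] + 5.0)

    def test_subset_moves_only_subset_and_preserves_distances(self):
        strip = SurfaceMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 2, 0], [1, 2, 0]]),
            np.array([[0, 1, 2], [1, 3, 2], [2, 3, 4], [3, 5, 4]]),
        )
        subset = np.array([4, 5, 2, 3])
        T = rotation_about_axis(Axis3D.through([0, 1, 0], [1, 0, 0], "h"), 10.0)
        out = apply_transform(strip, T, subset)
        untouched = np.array([0, 1])
        assert np.array_equal(out.vertices[untouched], strip.vertices[untouched])
        before = np.linalg.norm(
            strip.vertices[subset][:, None] - strip.vertices[subset][None], axis=-1
        )
        after = np.linalg.norm(
            out.vertices[subset][:, None] - out.vertices[subset][None], axis=-1
        )
        np.testing.assert_allclose(after, before, rtol=1e-9, atol=1e-9)

    def test_out_of_range_subset_rejected(self, unit_cube):
        with pytest.raises(IndexError):
            apply_transform(unit_cube, RigidTransform.identity(), [99])


class TestClassifyByPlane:
    PLANE = Plane([0.0, 0.0, 0.0], [0.0, 0.0, 1.0])

    def test_two_points_either_side(self):
        mesh = SurfaceMesh(np.array([[0.0, 0, 1], [0, 0, -1], [1, 0, 2]]), np.array([[0, 1, 2]]))
        prox, dist = classify_by_plane(mesh, self.PLANE)
        assert set(prox) == {0, 2} and set(dist) == {1}

    def test_all_below_gives_empty_proximal_with_warning(self):
        mesh = SurfaceMesh(np.array([[0.0, 0, -1], [1, 0, -2], [0, 1, -3]]), np.array([[0, 1, 2]]))
        with pytest.warns(UserWarning):
            prox, dist = classify_by_plane(mesh, self.PLANE)
        assert prox.size == 0 and dist.size == 3

    def test_ties_go_distal(self):
        mesh = SurfaceMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 1]]), np.array([[0, 1, 2]]))
        prox, dist = classify_by_plane(mesh, self.PLANE)
        assert set(dist) == {0, 1} and set(prox) == {2}

    def test_cube_cut_mid_height(self, unit_cube):
        prox, dist = classify_by_plane(unit_cube, Plane([0, 0, 0.5], [0, 0, 1.0]))
        assert len(prox) == 4 and len(dist) == 4
        assert np.all(unit_cube.vertices[prox][:, 2] == 1.0)

    def test_invariant_to_reindexing(self, unit_cube):
        perm = np.array([3, 1, 4, 0, 7, 5, 2, 6])
        inv = np.argsort(perm)
        remeshed = SurfaceMesh(unit_cube.vertices[perm], inv[unit_cube.faces])
        plane = Plane([0, 0, 0.5], [0, 0, 1.0])
        prox_a, _ = classify_by_plane(unit_cube, plane)
        prox_b, _ = classify_by_plane(remeshed, plane)
        assert set(map(tuple, unit_cube.vertices[prox_a])) == set(
            map(tuple, remeshed.vertices[prox_b])
        )


class TestCropMesh:
    def test_keep_all_is_identity_up_to_indexing(self, unit_cube):
        out = crop_mesh(unit_cube, np.arange(8))
        assert np.array_equal(out.vertices, unit_cube.vertices)
        assert out.n_faces == unit_cube.n_faces

    def test_cube_proximal_half(self, unit_cube):
        prox, _ = classify_by_plane(unit_cube, Plane([0, 0, 0.5], [0, 0, 1.0]))
        out = crop_mesh(unit_cube, prox)
        assert out.n_vertices == 4
        # only the top face's two triangles survive
        assert out.n_faces == 2
        assert np.all(out.vertices[:, 2] == 1.0)

    def test_zero_face_result_flagged(self, unit_cube):
        with pytest.warns(UserWarning, match="zero faces"):
            out = crop_mesh(unit_cube, [0, 3, 5])
        assert out.n_faces == 0 and out.n_vertices == 3

    def test_empty_keep_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            crop_mesh(unit_cube, [])


class TestValidation:
    def test_rigid_transform_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_rigid_transform_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_mesh_rejects_bad_faces(self):
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
        with pytest.raises(ValueError):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 1]]))

    def test_mirror_reverses_winding(self, unit_cube):
        out = mirror_mesh(unit_cube)
        assert np.array_equal(out.faces, unit_cube.faces[:, ::-1])
        assert np.array_equal(out.vertices[:, 0], -unit_cube.vertices[:, 0])
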