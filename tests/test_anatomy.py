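"""Tibial frame, M0, cutting plane and hinge-axis construction."""

import numpy as np
import pytest

from owhto.anatomy import (
    HingeAxesConfig,
    LandmarkSet,
    build_cutting_plane,
    build_hinge_axes,
    build_tibial_frame,
    locate_m0,
    normalize_to_frame,
)
from owhto.geometry import RigidTransform, SurfaceMesh, rotation_about_axis, Axis3D
from scipy.spatial.transform import Rotation


def make_landmarks(**overrides) -> LandmarkSet:
    pts = {
        "acl_insertion": [0.0, 10.0, 350.0],
        "pcl_insertion": [0.0, -10.0, 350.0],
        "distal_articular_center": [0.0, 0.0, 0.0],
        "fibular_head": [45.0, -10.0, 385.0],
        "medial_plateau_edge": [-38.0, 0.0, 400.0],
        "lateral_plateau_edge": [42.0, 0.0, 400.0],
        "hip_center": [15.0, 0.0, 500.0],
        "distal_tibia_center": [0.0, 0.0, 0.0],
    }
    pts.update(overrides)
    return LandmarkSet(pts)


class TestTibialFrame:
    def test_axis_aligned_landmarks(self):
        f = build_tibial_frame(make_landmarks())
        np.testing.assert_allclose(f.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(f.z_axis, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.y_axis, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f.x_axis, [1, 0, 0], atol=1e-12)

    def test_translation_equivariance(self):
        lm = make_landmarks()
        shifted = lm.transform(RigidTransform(np.eye(3), [5.0, 5.0, 5.0]))
        f = build_tibial_frame(shifted)
        np.testing.assert_allclose(f.origin, [5, 5, 5], atol=1e-12)
        np.testing.assert_allclose(f.basis, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        T = RigidTransform(R, rng.normal(scale=40.0, size=3))
        lm = make_landmarks()
        f0 = build_tibial_frame(lm)
        f1 = build_tibial_frame(lm.transform(T))
        np.testing.assert_allclose(f1.origin, T.apply(f0.origin), atol=1e-9)
        np.testing.assert_allclose(f1.basis, R @ f0.basis, atol=1e-9)

    def test_rotation_about_z_by_17_degrees(self):
        T = rotation_about_axis(Axis3D.through([0, 0, 0], [0, 0, 1], "z"), 17.0)
        f0 = build_tibial_frame(make_landmarks())
        f1 = build_tibial_frame(make_landmarks().transform(T))
        np.testing.assert_allclose(f1.basis, T.rotation @ f0.basis, atol=1e-9)

    def test_degenerate_cruciate_axis_rejected(self):
        lm = make_landmarks(acl_insertion=[0, 0, 360.0], pcl_insertion=[0, 0, 340.0])
        with pytest.raises(ValueError):
            build_tibial_frame(lm)

    def test_normalize_round_trip(self):
        rng = np.random.default_rng(3)
        mesh = SurfaceMesh(rng.normal(scale=30, size=(20, 3)), np.array([[0, 1, 2]]))
        lm = make_landmarks().transform(
            RigidTransform(Rotation.from_euler("xyz", [10, 5, -20], degrees=True).as_matrix(),
                           [10.0, -30.0, 4.0])
        )
        f = build_tibial_frame(lm)
        normed = normalize_to_frame(mesh, f)
        back = f.frame_to_world().apply(normed.vertices)
        np.testing.assert_allclose(back, mesh.vertices, atol=1e-9)


class TestM0:
    def test_default_offset(self):
        lm = make_landmarks(medial_plateau_edge=[-38.0, 0.0, 400.0])
        np.testing.assert_allclose(locate_m0(lm), [-38, 0, 365], atol=1e-12)

    def test_zero_offset_is_medial_edge(self):
        lm = make_landmarks()
        np.testing.assert_allclose(locate_m0(lm, 0.0), lm["medial_plateau_edge"])

    def test_offset_linearity(self):
        lm = make_landmarks()
        d = locate_m0(lm, 10.0) - locate_m0(lm, 35.0)
        np.testing.assert_allclose(d, [0, 0, 25.0], atol=1e-12)

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            locate_m0(make_landmarks(), -1.0)


class TestCuttingPlane:
    def test_contains_both_points_and_orientation(self):
        lm = make_landmarks()
        plane = build_cutting_plane(lm)
        m0 = locate_m0(lm)
        assert abs(plane.signed_distance(m0)[0]) < 1e-9
        assert abs(plane.signed_distance(lm["fibular_head"])[0]) < 1e-9
        assert abs(plane.normal[1]) < 1e-12
        assert plane.normal[2] > 0

    def test_equal_heights_give_horizontal_plane(self):
        lm = make_landmarks(fibular_head=[45.0, -10.0, 365.0])  # same z as M0
        plane = build_cutting_plane(lm)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)

    def test_y_translation_invariance_of_normal(self):
        lm1 = make_landmarks()
        lm2 = make_landmarks(fibular_head=[45.0, 30.0, 385.0])
        np.testing.assert_allclose(
            build_cutting_plane(lm1).normal, build_cutting_plane(lm2).normal, atol=1e-12
        )

    def test_vertically_stacked_points_rejected(self):
        lm = make_landmarks(fibular_head=[-38.0, 5.0, 385.0])  # directly above M0
        with pytest.raises(ValueError):
            build_cutting_plane(lm)


class TestHingeAxes:
    def test_defaults_lie_in_plane(self, planning):
        plane, axes = planning["plane"], planning["axes"]
        assert [a.label for a in axes] == ["axis1", "axis2", "axis3"]
        for ax in axes:
            assert abs(ax.direction @ plane.normal) < 1e-9
            assert abs(plane.signed_distance(ax.point)[0]) < 1e-6

    def test_explicit_l_point_on_horizontal_plane(self):
        lm = make_landmarks(
            fibular_head=[45.0, -10.0, 365.0],
            m0=[-38.0, 0.0, 365.0],
            l1=[40.0, 0.0, 365.0],
        )
        plane = build_cutting_plane(lm)
        axes = build_hinge_axes(plane, lm)
        np.testing.assert_allclose(axes[0].point, [40, 0, 365], atol=1e-9)
        np.testing.assert_allclose(axes[0].direction, [0, 1, 0], atol=1e-12)

    def test_collinear_l0_l3_give_anteroposterior_axis3(self):
        lm = make_landmarks(
            fibular_head=[45.0, -10.0, 365.0],
            l0=[40.0, -10.0, 365.0],
            l3=[40.0, 15.0, 365.0],
        )
        plane = build_cutting_plane(lm)
        axes = build_hinge_axes(plane, lm)
        np.testing.assert_allclose(axes[2].direction, [0, 1, 0], atol=1e-12)

    def test_far_l_point_rejected_and_near_projected(self):
        lm_far = make_landmarks(
            fibular_head=[45.0, -10.0, 365.0], l1=[40.0, 0.0, 380.0]
        )
        plane = build_cutting_plane(lm_far)
        with pytest.raises(ValueError):
            build_hinge_axes(plane, lm_far)
        lm_near = make_landmarks(
            fibular_head=[45.0, -10.0, 365.0], l1=[40.0, 0.0, 368.0]
        )
        with pytest.warns(UserWarning, match="projecting"):
            axes = build_hinge_axes(build_cutting_plane(lm_near), lm_near)
        assert abs(build_cutting_plane(lm_near).signed_distance(axes[0].point)[0]) < 1e-9

    def test_spacing_between_first_two_axes(self, planning):
        a1, a2 = planning["axes"][:2]
        # parallel anteroposterior axes separated by the configured 10 mm
        gap = np.linalg.norm(np.cross(a1.direction, a2.point - a1.point))
        assert gap == pytest.approx(HingeAxesConfig().axis_spacing_mm, abs=0.2)


class TestLandmarkSet:
    def test_missing_required_name_reported(self):
        pts = make_landmarks().points.copy()
        del pts["hip_center"]
        with pytest.raises(ValueError, match="hip_center"):
            LandmarkSet(pts)

    def test_left_side_mirroring(self):
        lm = LandmarkSet(make_landmarks().points, side="left")
        r = lm.mirrored_to_right()
        assert r.side == "right"
        np.testing.assert_allclose(
            r["fibular_head"], [-45.0, -10.0, 385.0], atol=1e-12
        )

    def test_unknown_names_preserved(self):
        pts = dict(make_landmarks().points)
        pts["tibial_tuberosity"] = [5.0, 30.0, 360.0]
        lm = LandmarkSet(pts)
        assert "tibial_tuberosity" in lm
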