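"""Surrogate bone generator and ground-truth postoperative manufacture."""

import numpy as np
import pytest
import trimesh

from owhto.alignment import mechanical_line, plateau_crossing_pct
from owhto.anatomy import build_cutting_plane, build_hinge_axes, build_tibial_frame, normalize_to_frame
from owhto.geometry import crop_mesh
from owhto.registration import compare_model
from owhto.simulate import OsteotomyPlan, simulate_osteotomy
from owhto.synthetic import (
    TibiaParams,
    generate_tibia,
    make_virtual_postop,
    random_rigid_offset,
    recovery_experiment,
)


class TestGenerateTibia:
    def test_deterministic(self, coarse_params, coarse_tibia):
        mesh2, lm2 = generate_tibia(coarse_params)
        mesh, lm = coarse_tibia
        assert np.array_equal(mesh.vertices, mesh2.vertices)
        assert np.array_equal(mesh.faces, mesh2.faces)
        for k in lm.points:
            assert np.array_equal(lm[k], lm2[k])

    def test_tibia_component_watertight(self, coarse_tibia):
        mesh, _ = coarse_tibia
        tib = np.flatnonzero(mesh.vertex_labels == "tibia")
        m = crop_mesh(mesh, tib)
        tm = trimesh.Trimesh(m.vertices, m.faces, process=False)
        assert tm.is_watertight
        assert tm.volume > 0  # consistent outward winding

    def test_plateau_width_echoes_parameter(self, coarse_tibia):
        _, lm = coarse_tibia
        width = np.linalg.norm(lm["lateral_plateau_edge"] - lm["medial_plateau_edge"])
        assert width == pytest.approx(80.0, abs=1e-9)

    def test_neutral_alignment_crosses_at_fifty_percent(self):
        _, lm = generate_tibia(TibiaParams(varus_angle=0.0, mesh_edge_length=6.0))
        line = mechanical_line(lm["hip_center"], lm["distal_tibia_center"])
        pct = plateau_crossing_pct(line, lm["medial_plateau_edge"], lm["lateral_plateau_edge"])
        assert pct == pytest.approx(50.0, abs=1e-9)

    def test_varus_fixture_crosses_medially(self, coarse_tibia):
        _, lm = coarse_tibia
        line = mechanical_line(lm["hip_center"], lm["distal_tibia_center"])
        pct = plateau_crossing_pct(line, lm["medial_plateau_edge"], lm["lateral_plateau_edge"])
        assert pct < 40.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            TibiaParams(varus_angle=30.0)
        with pytest.raises(ValueError):
            TibiaParams(mesh_edge_length=20.0)


@pytest.fixture(scope="module")
def ctx(planning, coarse_params):
    axis2 = next(a for a in planning["axes"] if a.label == "axis2")
    plan = OsteotomyPlan(planning["plane"], axis2, 10.0)
    return {**planning, "plan": plan, "params": coarse_params}


class TestMakeVirtualPostop:
    def test_no_vertex_identity_with_preop(self, ctx):
        postop, _ = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"], params=ctx["params"], frame=ctx["frame"]
        )
        sim = simulate_osteotomy(ctx["mesh"], ctx["plan"])
        a = {tuple(np.round(v, 6)) for v in sim.mesh.vertices}
        b = {tuple(np.round(v, 6)) for v in postop.vertices}
        # only the axial pole points of the two closed components are
        # sampling-independent construction points; nothing else may match
        assert len(a & b) <= 4

    def test_noiseless_postop_close_to_simulation(self, ctx):
        postop, gt = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"], params=ctx["params"], frame=ctx["frame"]
        )
        sim = simulate_osteotomy(ctx["mesh"], ctx["plan"])
        _, dist = compare_model(sim, postop, ctx["plane"])
        # pure resampling difference at 3 mm edges
        assert dist.mean_mm < 0.35
        assert gt.applied_noise_sigma == 0.0

    def test_noise_moves_mean_towards_half_normal_expectation(self, ctx):
        postop, _ = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"],
            params=ctx["params"], frame=ctx["frame"], sigma_mm=0.1, seed=3,
        )
        sim = simulate_osteotomy(ctx["mesh"], ctx["plan"])
        _, dist = compare_model(sim, postop, ctx["plane"])
        # E|N(0, 0.1)| ~ 0.08 mm plus discretisation, bounded well above
        assert dist.mean_mm < 0.45

    def test_deterministic_given_seed(self, ctx):
        a, _ = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"],
            params=ctx["params"], frame=ctx["frame"], sigma_mm=0.2, patch_fraction=0.05, seed=9,
        )
        b, _ = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"],
            params=ctx["params"], frame=ctx["frame"], sigma_mm=0.2, patch_fraction=0.05, seed=9,
        )
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_patch_fraction_achieved_and_distal(self, ctx):
        postop, gt = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"],
            params=ctx["params"], frame=ctx["frame"], patch_fraction=0.1, seed=1,
        )
        assert gt.deleted_patch_fraction == pytest.approx(0.1, abs=0.01)
        full, _ = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"], params=ctx["params"], frame=ctx["frame"]
        )
        assert postop.n_vertices < full.n_vertices

    def test_excessive_patch_rejected(self, ctx):
        with pytest.raises(ValueError):
            make_virtual_postop(
                ctx["mesh"], ctx["lm"], ctx["plan"],
                params=ctx["params"], frame=ctx["frame"], patch_fraction=0.6,
            )

    def test_offset_is_recorded(self, ctx):
        rng = np.random.default_rng(5)
        off = random_rigid_offset(rng, 10.0, 10.0)
        _, gt = make_virtual_postop(
            ctx["mesh"], ctx["lm"], ctx["plan"],
            params=ctx["params"], frame=ctx["frame"], rigid_offset=off,
        )
        assert np.array_equal(gt.applied_rigid_offset.rotation, off.rotation)


class TestRandomRigidOffset:
    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        T = random_rigid_offset(rng, 10.0, 10.0)
        assert T.rotation_angle_deg <= 10.0
        assert np.linalg.norm(T.translation) <= 10.0


class TestRecoveryExperiment:
    def test_recovers_known_plan_on_coarse_fixture(self, coarse_params):
        rep = recovery_experiment(
            coarse_params, axis_label="axis1", theta_true=8.0, sigma_mm=0.05,
            patch_fraction=0.05, seed=21,
        )
        assert rep.recovered_axis == "axis1"
        assert rep.recovered_theta == 8.0
        assert rep.exact
        assert rep.min_mean_mm < 0.5
        assert len(rep.table.rows) == 60
        assert rep.selection, "acceptable candidates expected on the varus fixture"

    def test_unknown_axis_rejected(self, coarse_params):
        with pytest.raises(ValueError):
            recovery_experiment(coarse_params, axis_label="axis9")
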