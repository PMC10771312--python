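"""Parametric proximal-tibia surrogate and ground-truth postoperative meshes.

No CT data ship with this package, so every stage is exercised on a
deterministic parametric bone: a closed surface of elliptical cross-sections
(tapered shaft, metaphyseal flare, elliptical plateau cap, mild distal
flare), bowed into varus over a smooth transition zone at the proximal
metaphysis, with a small ellipsoidal fibular head as a separate labelled
component.  All anatomical landmarks are computed analytically from the
parameters, so frames, planes and hinge axes are exact by construction.

The surrogate is deliberately simple — no tibial spines, no tuberosity —
because every downstream check is geometric, not anatomical.

Ground-truth "postoperative" meshes are produced by applying a known
osteotomy plan to an *independently sampled* regeneration of the same
surface (shifted angular phase, finer edge length, hence no vertex identity
with the preoperative mesh), then optionally adding Gaussian displacement
along vertex normals (segmentation noise), deleting a connected patch on the
medial distal cortex (the manually removed fixation plate), and applying a
rigid offset (scanner frame mismatch).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .anatomy import (
    AnatomicalFrame,
    HingeAxesConfig,
    LandmarkSet,
    build_cutting_plane,
    build_hinge_axes,
    build_tibial_frame,
    locate_m0,
    normalize_to_frame,
)
from .alignment import AlignmentConfig, select_acceptable
from .geometry import RigidTransform, SurfaceMesh, apply_transform
from .registration import DistanceTable, ICPOptions, grid_search
from .simulate import OsteotomyPlan, generate_grid, simulate_osteotomy

__all__ = [
    "TibiaParams",
    "GroundTruth",
    "RecoveryReport",
    "generate_tibia",
    "make_virtual_postop",
    "random_rigid_offset",
    "recovery_experiment",
]


@dataclass(frozen=True)
class TibiaParams:
    """Geometry of the surrogate tibia (all lengths in millimetres).

    The defaults approximate an adult tibia: 340 mm shaft, 80 x 55 mm
    plateau, 8 degrees of varus bow at the proximal metaphysis (the deformity
    the osteotomy corrects).  ``phase`` shifts the angular sampling of every
    ring; regenerating with a different phase/edge length yields the same
    surface with entirely different vertices.
    """

    shaft_length: float = 340.0
    shaft_radius: float = 14.0
    plateau_width_ml: float = 80.0
    plateau_depth_ap: float = 55.0
    varus_angle: float = 8.0
    fibular_head_offset: tuple[float, float, float] = (7.0, -8.0, -22.0)
    fibular_head_radius: float = 8.0
    mesh_edge_length: float = 1.5
    femur_length: float = 400.0
    phase: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shaft_length",
            "shaft_radius",
            "plateau_width_ml",
            "plateau_depth_ap",
            "fibular_head_radius",
            "mesh_edge_length",
            "femur_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.varus_angle <= 25.0):
            raise ValueError("varus_angle must lie in [0, 25] degrees")
        if self.mesh_edge_length > min(self.plateau_width_ml, self.plateau_depth_ap) / 4:
            raise ValueError("mesh_edge_length too coarse for the plateau")


@dataclass
class GroundTruth:
    """Exactly what was applied when manufacturing a virtual postop mesh."""

    plan: OsteotomyPlan
    applied_noise_sigma: float
    applied_rigid_offset: RigidTransform
    deleted_patch_fraction: float
    seed: int


def _smoothstep(t: np.ndarray | float) -> np.ndarray | float:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan's approximation
    return math.pi * (3.0 * (a + b) - math.sqrt((3.0 * a + b) * (a + 3.0 * b)))


def _closed_revolution(rings: list[tuple[float, float, float]], n: int, phase: float,
                       bottom_pole: np.ndarray, top_pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed triangulated surface from stacked elliptical rings plus poles.

    ``rings`` is a list of (z, a, b) with a/b the ML/AP semi-axes; all rings
    share the vertex count ``n`` so consecutive rings join as quad strips.
    """
    phi = 2.0 * math.pi * (np.arange(n) + phase) / n
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    verts = [bottom_pole.reshape(1, 3)]
    for z, a, b in rings:
        ring = np.column_stack([a * cos_p, b * sin_p, np.full(n, z)])
        verts.append(ring)
    verts.append(top_pole.reshape(1, 3))
    V = np.vstack(verts)

    faces = []
    j = np.arange(n)
    jn = (j + 1) % n
    # bottom fan (wound so normals point away from the interior)
    faces.append(np.column_stack([np.zeros(n, dtype=np.int64), 1 + jn, 1 + j]))
    for r in range(len(rings) - 1):
        lo = 1 + r * n
        hi = lo + n
        faces.append(np.column_stack([lo + j, lo + jn, hi + j]))
        faces.append(np.column_stack([lo + jn, hi + jn, hi + j]))
    top_start = 1 + (len(rings) - 1) * n
    apex = len(V) - 1
    faces.append(np.column_stack([top_start + j, top_start + jn, np.full(n, apex, dtype=np.int64)]))
    return V, np.vstack(faces).astype(np.int64)


def _tibia_rings(p: TibiaParams) -> list[tuple[float, float, float]]:
    L = p.shaft_length
    a0, b0 = p.shaft_radius, 0.8 * p.shaft_radius
    A, B = p.plateau_width_ml / 2.0, p.plateau_depth_ap / 2.0
    flare_z = 60.0  # metaphyseal flare extent
    ankle_z = 30.0  # mild distal flare

    dz = 0.87 * p.mesh_edge_length
    nz = max(8, int(round(L / dz)) + 1)
    zs = np.linspace(0.0, L, nz)

    rings = []
    for z in zs:
        s = _smoothstep((z - (L - flare_z)) / flare_z)
        a = a0 + s * (A - a0)
        b = b0 + s * (B - b0)
        ankle = 1.0 + 0.3 * _smoothstep((ankle_z - z) / ankle_z)
        a *= ankle
        b *= ankle
        # collapse the extreme rings slightly inwards so the poles close cleanly
        if z <= 0.0:
            a, b = a * 0.999, b * 0.999
        rings.append((float(z), float(a), float(b)))

    # plateau cap: shrinking elliptical rings at z = L
    k_cap = max(2, int(round(A / p.mesh_edge_length)))
    for k in range(1, k_cap):
        f = 1.0 - k / k_cap
        rings.append((L, A * f, B * f))
    # distal cap rings at z = 0, growing outwards from the bottom pole
    cap0 = []
    a_bot = rings[0][1]
    b_bot = rings[0][2]
    k0 = max(2, int(round(a_bot / p.mesh_edge_length)))
    for k in range(1, k0):
        f = k / k0
        cap0.append((0.0, a_bot * f, b_bot * f))
    return cap0 + rings


def _varus_map(p: TibiaParams):
    """Smoothly blended varus rotation about the anteroposterior axis.

    Returns a function mapping (n, 3) straight-bone points to the bowed bone.
    The rotation angle ramps from zero below the metaphyseal transition zone
    to the full varus angle above it; the pivot sits on the bone axis at the
    base of the zone.  The full-angle region (plateau and everything above)
    is mapped rigidly, so plateau landmarks stay exact.
    """
    L = p.shaft_length
    zone_lo, zone_hi = L - 65.0, L - 15.0
    pivot = np.array([0.0, 0.0, zone_lo])

    def bend(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        beta = -np.radians(p.varus_angle) * _smoothstep(
            (pts[:, 2] - zone_lo) / (zone_hi - zone_lo)
        )
        rel = pts - pivot
        cb, sb = np.cos(beta), np.sin(beta)
        out = rel.copy()
        out[:, 0] = cb * rel[:, 0] + sb * rel[:, 2]
        out[:, 2] = -sb * rel[:, 0] + cb * rel[:, 2]
        return out + pivot

    return bend


def _uv_sphere(center: np.ndarray, radius: float, edge: float, phase: float) -> tuple[np.ndarray, np.ndarray]:
    n_lat = max(4, int(round(math.pi * radius / edge)))
    n_lon = max(6, int(round(2.0 * math.pi * radius / edge)))
    lat = np.linspace(0.0, math.pi, n_lat + 1)[1:-1]
    rings = [(center[2] + radius * math.cos(t), radius * math.sin(t), radius * math.sin(t)) for t in lat]
    top = center + np.array([0.0, 0.0, radius])
    bot = center - np.array([0.0, 0.0, radius])
    # reuse the ring builder around the sphere centre (rings ordered top->down)
    V, F = _closed_revolution(
        [(z, a, b) for z, a, b in rings[::-1]], n_lon, phase, bot, top
    )
    V[:, 0] += center[0]
    V[:, 1] += center[1]
    return V, F


def generate_tibia(params: TibiaParams | None = None) -> tuple[SurfaceMesh, LandmarkSet]:
    """Watertight surrogate tibia plus analytically exact landmarks.

    Deterministic: the output is a pure function of the parameters.  The
    fibular head is a separate component labelled ``"fibula"``; tibial
    vertices are labelled ``"tibia"``.
    """
    p = params or TibiaParams()
    L = p.shaft_length
    A = p.plateau_width_ml / 2.0

    perim = _ellipse_perimeter(A, p.plateau_depth_ap / 2.0)
    n = max(12, int(round(perim / p.mesh_edge_length)))
    rings = _tibia_rings(p)
    V, F = _closed_revolution(
        rings, n, p.phase, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, L])
    )
    bend = _varus_map(p)
    V = bend(V)

    lat_edge = bend(np.array([A, 0.0, L]))[0]
    med_edge = bend(np.array([-A, 0.0, L]))[0]
    acl = bend(np.array([0.0, 8.0, L]))[0]
    pcl = bend(np.array([0.0, -12.0, L]))[0]
    plateau_center = bend(np.array([0.0, 0.0, L]))[0]

    # plateau normal after the (rigid) full-angle bend
    beta = -math.radians(p.varus_angle)
    plateau_normal = np.array([math.sin(beta), 0.0, math.cos(beta)])
    hip = plateau_center + p.femur_length * plateau_normal

    apex = lat_edge + np.asarray(p.fibular_head_offset, dtype=float)
    fib_center = apex - np.array([0.0, 0.0, p.fibular_head_radius])
    Vf, Ff = _uv_sphere(fib_center, p.fibular_head_radius, p.mesh_edge_length, p.phase)

    vertices = np.vstack([V, Vf])
    faces = np.vstack([F, Ff + len(V)])
    labels = np.array(["tibia"] * len(V) + ["fibula"] * len(Vf))
    mesh = SurfaceMesh(vertices, faces, labels)

    lm = LandmarkSet(
        {
            "acl_insertion": acl,
            "pcl_insertion": pcl,
            "distal_articular_center": np.zeros(3),
            "fibular_head": apex,
            "medial_plateau_edge": med_edge,
            "lateral_plateau_edge": lat_edge,
            "hip_center": hip,
            "distal_tibia_center": np.zeros(3),
        },
        side="right",
    )
    return mesh, lm


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    tri = mesh.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return vn / norms


def _face_adjacency(faces: np.ndarray) -> list[np.ndarray]:
    """Faces sharing an edge, as an adjacency list."""
    f = np.repeat(np.arange(len(faces)), 3)
    e = np.sort(
        np.stack([faces[:, [0, 1, 2]].reshape(-1), faces[:, [1, 2, 0]].reshape(-1)], axis=1),
        axis=1,
    )
    order = np.lexsort((e[:, 1], e[:, 0]))
    e_s, f_s = e[order], f[order]
    same = np.all(e_s[1:] == e_s[:-1], axis=1)
    pairs = np.column_stack([f_s[:-1][same], f_s[1:][same]])
    adj: list[list[int]] = [[] for _ in range(len(faces))]
    for u, v in pairs:
        adj[u].append(v)
        adj[v].append(u)
    return [np.asarray(a, dtype=np.int64) for a in adj]


def _delete_plate_patch(
    mesh: SurfaceMesh, lm: LandmarkSet, plan: OsteotomyPlan, fraction: float
) -> tuple[SurfaceMesh, float]:
    """Remove a connected patch of faces on the medial cortex below the cut.

    Grown breadth-first over face adjacency, restricted to distal faces, from
    the face nearest the plate centre (medial cortex ~15 mm below M0) until
    the requested fraction of the total surface area is removed.
    """
    tri = mesh.triangles()
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    target = fraction * float(areas.sum())

    centroids = tri.mean(axis=1)
    below = plan.plane.signed_distance(centroids) <= 0.0
    if mesh.vertex_labels is not None:
        tibial = np.all(np.asarray(mesh.vertex_labels)[mesh.faces] == "tibia", axis=1)
        below &= tibial
    plate_center = locate_m0(lm) + np.array([0.0, 0.0, -15.0])
    eligible = np.flatnonzero(below)
    if eligible.size == 0:
        raise ValueError("no distal faces available for patch deletion")
    seed_face = eligible[np.argmin(np.linalg.norm(centroids[eligible] - plate_center, axis=1))]

    adj = _face_adjacency(mesh.faces)
    removed = np.zeros(len(mesh.faces), dtype=bool)
    queue = deque([seed_face])
    removed[seed_face] = True
    acc = areas[seed_face]
    while queue and acc < target:
        f = queue.popleft()
        for g in adj[f]:
            if not removed[g] and below[g]:
                removed[g] = True
                acc += areas[g]
                queue.append(g)
                if acc >= target:
                    break
    achieved = float(acc / areas.sum())
    if achieved < fraction * 0.95:
        warnings.warn(
            f"plate patch capped at {achieved:.1%} (requested {fraction:.1%}): "
            "ran out of distal faces",
            stacklevel=2,
        )
    faces = mesh.faces[~removed]
    keep = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    labels = None if mesh.vertex_labels is None else mesh.vertex_labels[keep]
    return SurfaceMesh(mesh.vertices[keep], remap[faces], labels), achieved


def random_rigid_offset(
    rng: np.random.Generator,
    max_angle_deg: float,
    max_translation_mm: float,
    center=None,
) -> RigidTransform:
    """Random proper rigid transform with bounded magnitude (frame offset).

    The rotation acts about ``center`` (e.g. the bone centroid) so that a
    10-degree scanner-pose mismatch means a 10-degree tilt of the object,
    not a swing about a distant origin.
    """
    axis = rng.normal(size=3)
    axis = axis / np.linalg.norm(axis)
    angle = rng.uniform(0.0, np.radians(max_angle_deg))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t_dir = rng.normal(size=3)
    t_dir = t_dir / np.linalg.norm(t_dir)
    t = rng.uniform(0.0, max_translation_mm) * t_dir
    if center is not None:
        c = np.asarray(center, dtype=float).reshape(3)
        t = t + c - R @ c
    return RigidTransform(R, t)


def make_virtual_postop(
    preop: SurfaceMesh,
    lm: LandmarkSet,
    plan: OsteotomyPlan,
    *,
    params: TibiaParams | None = None,
    frame: AnatomicalFrame | None = None,
    sigma_mm: float = 0.0,
    rigid_offset: RigidTransform | None = None,
    patch_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[SurfaceMesh, GroundTruth]:
    """Manufacture a reference "postoperative" mesh with known ground truth.

    When ``params`` is given (with ``frame`` the frame the preoperative data
    were normalised into), the surface is regenerated at a shifted sampling
    (phase + finer edge length), guaranteeing no vertex identity with the
    preoperative mesh; otherwise the preoperative mesh is midpoint-subdivided
    as a weaker resampling.  The known plan is then applied, followed by
    Gaussian noise along vertex normals (s.d. ``sigma_mm``), deletion of the
    plate patch (``patch_fraction`` of total area, on the medial distal
    cortex) and the rigid offset.  Everything applied is recorded in the
    returned :class:`GroundTruth`; the output is deterministic given
    ``seed``.
    """
    if patch_fraction >= 0.5:
        raise ValueError("patch_fraction must be < 0.5")
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be non-negative")

    if params is not None:
        regen_params = replace(
            params,
            phase=params.phase + 0.5,
            mesh_edge_length=params.mesh_edge_length * 0.85,
        )
        base, base_lm = generate_tibia(regen_params)
        f = frame or build_tibial_frame(base_lm)
        base = normalize_to_frame(base, f)
    else:
        base = _midpoint_subdivide(preop)

    model = simulate_osteotomy(base, plan)
    mesh = model.mesh

    rng = np.random.default_rng(seed)
    if sigma_mm > 0:
        normals = _vertex_normals(mesh)
        mesh = mesh.copy()
        mesh.vertices = mesh.vertices + rng.normal(0.0, sigma_mm, mesh.n_vertices)[:, None] * normals

    achieved = 0.0
    if patch_fraction > 0:
        mesh, achieved = _delete_plate_patch(mesh, lm, plan, patch_fraction)

    offset = rigid_offset or RigidTransform.identity()
    if not offset.is_identity():
        mesh = apply_transform(mesh, offset)

    return mesh, GroundTruth(plan, sigma_mm, offset, achieved, seed)


def _midpoint_subdivide(mesh: SurfaceMesh) -> SurfaceMesh:
    """One 1:4 midpoint subdivision (fallback resampling for foreign meshes)."""
    import trimesh

    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    v, f = trimesh.remesh.subdivide(tm.vertices, tm.faces)
    return SurfaceMesh(v, f)


@dataclass
class RecoveryReport:
    """End-to-end ground-truth recovery: did the grid argmin find the plan?"""

    true_axis: str
    true_theta: float
    recovered_axis: str | None
    recovered_theta: float | None
    min_mean_mm: float | None
    table: DistanceTable
    selection: list[tuple[str, float, float]]
    ground_truth: GroundTruth

    @property
    def exact(self) -> bool:
        return self.recovered_axis == self.true_axis and self.recovered_theta == self.true_theta


def recovery_experiment(
    params: TibiaParams | None = None,
    axis_label: str = "axis2",
    theta_true: float = 10.0,
    *,
    sigma_mm: float = 0.1,
    patch_fraction: float = 0.1,
    offset_angle_deg: float = 10.0,
    offset_translation_mm: float = 10.0,
    theta_range=None,
    hinge_config: HingeAxesConfig | None = None,
    icp_opts: ICPOptions | None = None,
    alignment: AlignmentConfig | None = None,
    seed: int = 0,
) -> RecoveryReport:
    """Full pipeline on manufactured ground truth: simulate, register, recover.

    Generates the surrogate, normalises it, builds plane and hinge axes,
    manufactures a noisy/offset/holed postoperative mesh at the stated
    (axis, theta), sweeps the grid, and reports the recovered optimum, the
    minimum average surface distance and the Fujisawa-acceptable set.
    """
    p = params or TibiaParams()
    thetas = theta_range if theta_range is not None else None
    mesh0, lm0 = generate_tibia(p)
    f = build_tibial_frame(lm0)
    mesh = normalize_to_frame(mesh0, f)
    lm = lm0.transform(f.world_to_frame())
    plane = build_cutting_plane(lm)
    axes = build_hinge_axes(plane, lm, hinge_config)
    by_label = {a.label: a for a in axes}
    if axis_label not in by_label:
        raise ValueError(f"unknown hinge axis {axis_label!r}")
    plan = OsteotomyPlan(plane, by_label[axis_label], theta_true)

    rng = np.random.default_rng(seed)
    offset = random_rigid_offset(
        rng, offset_angle_deg, offset_translation_mm, center=mesh.vertices.mean(axis=0)
    )
    postop, gt = make_virtual_postop(
        mesh,
        lm,
        plan,
        params=p,
        frame=f,
        sigma_mm=sigma_mm,
        rigid_offset=offset,
        patch_fraction=patch_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    models = generate_grid(mesh, plane, axes, thetas)
    table, best = grid_search(models, postop, plane, icp_opts)
    selection = [
        (m.plan.axis.label, float(m.plan.theta), res.crossing_pct)
        for m, res in select_acceptable(models, lm, alignment)
    ]
    if best is None:
        return RecoveryReport(axis_label, theta_true, None, None, None, table, selection, gt)
    min_mean = float(table.rows["mean_mm"].min())
    return RecoveryReport(
        axis_label, theta_true, best[0], best[1], min_mean, table, selection, gt
    )
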