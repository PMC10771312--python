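"""Trimmed ICP registration and grid scoring against a postoperative mesh.

A simulated realignment is compared with a reference postoperative mesh in
two steps: (1) rigidly register the *distal* fragments — the part of the
tibia the osteotomy leaves untouched — with trimmed iterative closest point,
and (2) score the *proximal* fragments with the average surface distance.
Sweeping the whole (hinge axis x rotation angle) grid and taking the argmin
identifies the simulation closest to the reference realignment.

The ICP here is point-to-surface: correspondences are nearest points on the
target triangles and the rigid update is the SVD (Kabsch) fit.  Holes such
as the manually deleted fixation-plate region of a real postoperative
segmentation are tolerated by rejecting correspondences that land on an open
boundary of the target (the rim of a hole has no true counterpart) and by a
trimmed refinement that re-fits on the best fraction of correspondences
(default 0.9) once the descent has converged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceResult, SurfaceDistanceQuery, surface_distance
from .geometry import (
    Plane,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    classify_by_plane,
    crop_mesh,
)
from .simulate import SimulationModel

__all__ = [
    "ICPOptions",
    "RegistrationResult",
    "DistanceTable",
    "kabsch",
    "icp_register",
    "compare_model",
    "grid_search",
]


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Best rigid transform (no scaling) mapping paired source -> target points.

    Cross-covariance SVD solution; raises if fewer than three non-collinear
    correspondences are supplied.
    """
    src = np.asarray(source_points, dtype=float)
    dst = np.asarray(target_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 correspondences")
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    scale = np.linalg.norm(src - cs, axis=1).mean()
    if scale > 0 and S[1] / max(scale, 1e-12) ** 2 / len(src) < 1e-12:
        raise ValueError("correspondences are (near-)collinear; rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


@dataclass(frozen=True)
class ICPOptions:
    """Tuning knobs for trimmed ICP.

    trim_fraction: fraction of correspondences kept in the refinement
    phase, frozen by distance rank once the boundary-filtered descent has
    converged; 1.0 disables the refinement.  max_points: source vertices
    are subsampled (evenly strided, deterministic) beyond this count.
    """

    max_iterations: int = 100
    tolerance_mm: float = 1e-6
    trim_fraction: float = 0.9
    max_points: int = 2000
    initial: RigidTransform | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.trim_fraction <= 1.0):
            raise ValueError("trim_fraction must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Outcome of a rigid registration: transform maps source onto target."""

    transform: RigidTransform
    rms_mm: float
    n_iterations: int
    converged: bool


def icp_register(
    source: SurfaceMesh, target: SurfaceMesh, opts: ICPOptions | None = None
) -> RegistrationResult:
    """Trimmed point-to-surface ICP aligning ``source`` onto ``target``.

    Stops when the trimmed RMS changes by less than ``tolerance_mm`` between
    iterations, or at ``max_iterations`` (returned with ``converged=False``,
    never silently).
    """
    opts = opts or ICPOptions()
    if source.n_vertices == 0:
        raise ValueError("source mesh is empty")
    query = SurfaceDistanceQuery(target)  # rejects empty target
    boundary_tri = _boundary_triangles(target.faces)

    pts = source.vertices
    if len(pts) > opts.max_points:
        idx = np.unique(np.linspace(0, len(pts) - 1, opts.max_points).astype(np.int64))
        pts = pts[idx]

    # Outlier handling: a source point whose nearest target point falls on a
    # triangle at an open boundary (the rim of a hole or of the cut) has no
    # reliable correspondence and is excluded from every fit — this is what
    # makes holes such as the deleted plate region harmless.  Rank-trimming
    # every iteration would instead discard the distinctive geometry that
    # prevents the fit from sliding, so the trim fraction is applied only as
    # a frozen refinement once the boundary-filtered descent has converged.
    T = opts.initial or RigidTransform.identity()
    rms = np.inf
    total_it = 0

    def descend(active: np.ndarray, reject_boundary: bool) -> bool:
        nonlocal T, rms, total_it
        prev_rms = np.inf
        for _ in range(opts.max_iterations):
            total_it += 1
            d, cp, tri = query.query(T.apply(active), exact=False)
            if reject_boundary:
                keep = ~boundary_tri[tri]
                if keep.sum() < 3:
                    keep[:] = True
            else:
                keep = np.ones(len(d), dtype=bool)
            rms_now = float(np.sqrt(np.mean(d[keep] ** 2)))
            rms = rms_now
            if abs(prev_rms - rms_now) < opts.tolerance_mm:
                return True
            prev_rms = rms_now
            T = kabsch(active[keep], cp[keep])
        return False

    converged = descend(pts, True)
    if opts.trim_fraction < 1.0:
        d, _, tri = query.query(T.apply(pts), exact=False)
        ok = np.flatnonzero(~boundary_tri[tri])
        if ok.size < 3:
            ok = np.arange(len(pts))
        n_keep = max(3, math.ceil(opts.trim_fraction * ok.size))
        subset = ok[np.argpartition(d[ok], n_keep - 1)[:n_keep]]
        converged = descend(pts[subset], False)
    if not converged:
        warnings.warn(
            f"ICP did not converge in {opts.max_iterations} iterations (rms {rms:.4g} mm)",
            stacklevel=2,
        )
    return RegistrationResult(T, rms, total_it, converged)


def _boundary_triangles(faces: np.ndarray) -> np.ndarray:
    """Mask of triangles owning at least one open (unshared) edge."""
    e = np.sort(
        np.stack([faces[:, [0, 1, 2]].reshape(-1), faces[:, [1, 2, 0]].reshape(-1)], axis=1),
        axis=1,
    )
    f = np.repeat(np.arange(len(faces)), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    e_s, f_s = e[order], f[order]
    same = np.all(e_s[1:] == e_s[:-1], axis=1)
    shared = np.zeros(len(e_s), dtype=bool)
    shared[:-1][same] = True
    shared[1:][same] = True
    mask = np.zeros(len(faces), dtype=bool)
    mask[f_s[~shared]] = True
    return mask


def _distal_fragment(model: SimulationModel) -> SurfaceMesh:
    """Everything the simulated surgery left untouched (fixed fragment)."""
    fixed = np.setdiff1d(
        np.arange(model.mesh.n_vertices), model.proximal_indices, assume_unique=False
    )
    return crop_mesh(model.mesh, fixed)


def _proximal_crop(mesh: SurfaceMesh, plane: Plane) -> SurfaceMesh:
    """Proximal surface: faces fully above the plane, with their vertices.

    Vertices above the plane whose every face straddles it (isolated points,
    e.g. the tip of a component poking through the plane) carry no surface
    and would corrupt point-to-surface statistics, so the crop keeps only
    face-supported vertices.
    """
    proximal, _ = classify_by_plane(mesh, plane)
    above = np.zeros(mesh.n_vertices, dtype=bool)
    above[proximal] = True
    face_mask = np.all(above[mesh.faces], axis=1)
    supported = np.unique(mesh.faces[face_mask])
    if supported.size == 0:
        raise ValueError("no faces entirely proximal to the plane")
    return crop_mesh(mesh, supported)


def _register_postop_distal(
    postop: SurfaceMesh,
    target_distal: SurfaceMesh,
    plane: Plane,
    icp_opts: ICPOptions | None,
) -> RegistrationResult:
    """Two-pass distal registration of an arbitrarily offset postop mesh.

    Cropping the postoperative mesh at the plane before it is aligned
    misassigns vertices near the cut (the offset moves the bone relative to
    the plane), so the crop-and-register step is run twice: a first pass
    from the rough crop, then a re-crop at the aligned pose and a refining
    registration.  The returned transform is the composition.
    """
    _, rough_idx = classify_by_plane(postop, plane)
    reg1 = icp_register(crop_mesh(postop, rough_idx), target_distal, icp_opts)
    aligned = apply_transform(postop, reg1.transform)
    _, idx2 = classify_by_plane(aligned, plane)
    reg2 = icp_register(crop_mesh(aligned, idx2), target_distal, icp_opts)
    total = reg2.transform.compose(reg1.transform)
    return RegistrationResult(
        total, reg2.rms_mm, reg1.n_iterations + reg2.n_iterations, reg2.converged
    )


def compare_model(
    model: SimulationModel,
    postop: SurfaceMesh,
    plane: Plane,
    icp_opts: ICPOptions | None = None,
    direction: str = "symmetric",
) -> tuple[RegistrationResult, DistanceResult]:
    """Register on the distal fragments, score on the proximal fragments.

    The postoperative mesh (supplied in approximately the same frame) is
    cropped distal to the plane and registered onto the simulation's fixed
    fragment; the recovered transform is applied to the whole postoperative
    mesh, and the average surface distance is computed between the proximal
    fragments only.
    """
    reg = _register_postop_distal(postop, _distal_fragment(model), plane, icp_opts)
    postop_aligned = apply_transform(postop, reg.transform)
    dist = surface_distance(
        _proximal_crop(model.mesh, plane), _proximal_crop(postop_aligned, plane), direction
    )
    return reg, dist


@dataclass
class DistanceTable:
    """(axis, theta) -> average surface distance grid with provenance.

    ``rows`` is a DataFrame with columns axis, theta_deg, mean_mm, max_mm,
    rms_reg_mm, converged — one row per successfully compared grid model.
    """

    rows: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def best(self) -> tuple[str, float] | None:
        """Global argmin of mean_mm; ties broken by smaller theta, then axis label."""
        if len(self.rows) == 0:
            return None
        ordered = self.rows.sort_values(
            ["mean_mm", "theta_deg", "axis"], kind="mergesort"
        ).iloc[0]
        return str(ordered["axis"]), float(ordered["theta_deg"])


def grid_search(
    models: list[SimulationModel],
    postop: SurfaceMesh,
    plane: Plane,
    icp_opts: ICPOptions | None = None,
    direction: str = "symmetric",
    provenance: dict | None = None,
) -> tuple[DistanceTable, tuple[str, float] | None]:
    """Score every grid model against the postoperative mesh; return argmin.

    The rigid simulation leaves the distal fragment bit-identical across the
    grid, so the distal registration is computed once and reused for every
    model (verified; falls back to per-model registration if the fragments
    differ).  A model whose comparison fails is recorded as a missing row,
    not a fatal error.
    """
    if not models:
        raise ValueError("no models to compare")

    shared_distal = all(
        np.array_equal(m.proximal_indices, models[0].proximal_indices)
        and np.array_equal(
            np.delete(m.mesh.vertices, m.proximal_indices, axis=0),
            np.delete(models[0].mesh.vertices, models[0].proximal_indices, axis=0),
        )
        for m in models[1:]
    )

    records = []
    failures = []
    if shared_distal:
        reg = _register_postop_distal(postop, _distal_fragment(models[0]), plane, icp_opts)
        postop_aligned = apply_transform(postop, reg.transform)
        postop_prox = _proximal_crop(postop_aligned, plane)
        postop_query = SurfaceDistanceQuery(postop_prox)
        for m in models:
            try:
                dist = _symmetric_cached(
                    _proximal_crop(m.mesh, plane), postop_prox, postop_query, direction
                )
                records.append(_record(m, reg, dist))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures.append((m.plan.axis.label, m.plan.theta, str(exc)))
    else:
        for m in models:
            try:
                reg, dist = compare_model(m, postop, plane, icp_opts, direction)
                records.append(_record(m, reg, dist))
            except Exception as exc:  # noqa: BLE001
                failures.append((m.plan.axis.label, m.plan.theta, str(exc)))

    rows = pd.DataFrame(
        records, columns=["axis", "theta_deg", "mean_mm", "max_mm", "rms_reg_mm", "converged"]
    )
    table = DistanceTable(rows, provenance or {}, failures)
    return table, table.best()


def _symmetric_cached(
    query_mesh: SurfaceMesh,
    ref_mesh: SurfaceMesh,
    ref_query: SurfaceDistanceQuery,
    direction: str,
) -> DistanceResult:
    """surface_distance with the reference query structure reused across calls."""
    d_fwd = ref_query.query(query_mesh.vertices)[0]
    if direction == "one-sided":
        return DistanceResult(float(d_fwd.mean()), float(d_fwd.max()), d_fwd, "one-sided")
    d_rev = SurfaceDistanceQuery(query_mesh).query(ref_mesh.vertices)[0]
    mean = 0.5 * (float(d_fwd.mean()) + float(d_rev.mean()))
    return DistanceResult(mean, float(max(d_fwd.max(), d_rev.max())), d_fwd, "symmetric")


def _record(model: SimulationModel, reg: RegistrationResult, dist: DistanceResult) -> dict:
    return {
        "axis": model.plan.axis.label,
        "theta_deg": float(model.plan.theta),
        "mean_mm": dist.mean_mm,
        "max_mm": dist.max_mm,
        "rms_reg_mm": reg.rms_mm,
        "converged": bool(reg.converged),
    }
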