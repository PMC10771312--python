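"""Virtual medial open-wedge osteotomy: rotate the proximal fragment.

One simulated surgery is a rigid rotation of every tibial vertex above the
osteotomy plane about a hinge axis lying in that plane; the distal fragment
(and the fibula, which the medial procedure does not cut) stays fixed.  The
wedge gap is left unfilled — no new geometry is created, faces straddling the
plane simply stretch — mirroring how the realignment is modelled clinically.

Positive rotation angles always open the wedge medially (valgus correction):
the sign of the rotation is chosen per axis so that a point medial to the
hinge moves proximally, rather than trusting the axis direction's orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    Axis3D,
    Plane,
    RigidTransform,
    SurfaceMesh,
    apply_transform,
    classify_by_plane,
    rotation_about_axis,
    unit,
)

__all__ = [
    "OsteotomyPlan",
    "SimulationModel",
    "simulate_osteotomy",
    "generate_grid",
    "wedge_angle_check",
    "default_theta_range",
]

#: default correction-angle sweep, degrees
def default_theta_range() -> list[float]:
    return [float(t) for t in range(1, 21)]


_IN_PLANE_TOL = 1e-6


@dataclass(frozen=True)
class OsteotomyPlan:
    """Cutting plane + hinge axis + wedge-opening angle theta (degrees)."""

    plane: Plane
    axis: Axis3D
    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or not (0.0 <= self.theta <= 45.0):
            raise ValueError("theta must lie in [0, 45] degrees")
        if abs(float(self.plane.signed_distance(self.axis.point)[0])) > _IN_PLANE_TOL:
            raise ValueError("hinge axis point must lie in the cutting plane")
        if abs(self.axis.direction @ self.plane.normal) > _IN_PLANE_TOL:
            raise ValueError("hinge axis direction must lie in the cutting plane")


@dataclass
class SimulationModel:
    """One simulated postoperative shape.

    ``mesh`` holds the rotated proximal fragment and untouched distal
    fragment; ``transform`` is the signed rigid rotation that was applied to
    ``proximal_indices``.
    """

    mesh: SurfaceMesh
    plan: OsteotomyPlan
    transform: RigidTransform
    proximal_indices: np.ndarray


def _medial_opening_sign(plan: OsteotomyPlan) -> float:
    """Sign making positive theta raise the medial side (valgus opening).

    Probes a point medial to the hinge in the cutting plane: the correct
    rotation direction lifts it along the plane normal (proximally).
    """
    n = plan.plane.normal
    medial = unit(np.array([-1.0, 0.0, 0.0]) - (np.array([-1.0, 0.0, 0.0]) @ n) * n)
    probe = plan.axis.point + 60.0 * medial
    theta = plan.theta if plan.theta > 0 else 1.0  # direction test only
    lift = rotation_about_axis(plan.axis, theta).apply(probe) - probe
    return 1.0 if (lift @ n) >= 0 else -1.0


def simulate_osteotomy(
    preop: SurfaceMesh,
    plan: OsteotomyPlan,
    fixed_labels: tuple[str, ...] = ("fibula",),
) -> SimulationModel:
    """Rotate the proximal tibial fragment about the hinge axis by theta.

    The proximal vertex set comes from plane classification; vertices whose
    label is in ``fixed_labels`` (the fibula by default) never move.  The
    rotation sign is auto-corrected so the medial wedge opens; a correction
    is reported with a warning.
    """
    proximal, _ = classify_by_plane(preop, plan.plane)
    if preop.vertex_labels is not None and len(fixed_labels):
        keep = ~np.isin(preop.vertex_labels[proximal], fixed_labels)
        proximal = proximal[keep]
    if proximal.size == 0:
        raise ValueError("no movable vertices above the osteotomy plane")
    sign = _medial_opening_sign(plan)
    if sign < 0:
        warnings.warn(
            f"hinge {plan.axis.label or '?'}: rotation sign flipped to open the medial wedge",
            stacklevel=2,
        )
    transform = rotation_about_axis(plan.axis, sign * plan.theta)
    mesh = apply_transform(preop, transform, proximal)
    return SimulationModel(mesh, plan, transform, proximal)


def generate_grid(
    preop: SurfaceMesh,
    plane: Plane,
    axes: list[Axis3D],
    theta_range=None,
    fixed_labels: tuple[str, ...] = ("fibula",),
) -> list[SimulationModel]:
    """All (axis, theta) combinations in deterministic axis-major order.

    The default sweep is 1..20 degrees in 1-degree steps, giving 60 models
    for the three default hinge axes.
    """
    if not axes:
        raise ValueError("need at least one hinge axis")
    thetas = default_theta_range() if theta_range is None else [float(t) for t in theta_range]
    if any(t <= 0 for t in thetas):
        raise ValueError("sweep angles must be strictly positive")
    pairs = [(ax.label, t) for ax in axes for t in thetas]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (axis, theta) combinations in grid")
    return [
        simulate_osteotomy(preop, OsteotomyPlan(plane, ax, t), fixed_labels)
        for ax in axes
        for t in thetas
    ]


def wedge_angle_check(model: SimulationModel) -> float:
    """Wedge-opening angle (degrees) recovered from the applied transform.

    The dihedral angle between the preoperative cutting plane and its image
    under the fragment rotation equals the rotation magnitude because the
    hinge axis lies in the plane; recovering the angle from the rotation
    matrix measures exactly that.
    """
    return model.transform.rotation_angle_deg
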