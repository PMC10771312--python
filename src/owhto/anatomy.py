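"""Anatomical landmarks, the tibial coordinate frame, cutting plane and hinge axes.

The tibial frame is built from three landmarks (ACL and PCL insertions on the
plateau, centre of the distal articular surface): its z-axis runs distal to
proximal, y anterior, x lateral (right knee).  Left-knee inputs are mirrored
about the sagittal plane on load so every downstream computation assumes a
right knee.

The osteotomy (cutting) plane is obtained by rotating the horizontal plane
about the anteroposterior (y) axis until it contains both M0 — the medial cut
entry, a fixed offset (default 35 mm) inferior to the medial edge of the
articular surface — and the fibular head.  Hinge axes are in-plane lines near
the lateral cortex: two anteroposterior axes 10 mm apart and one oblique
axis, standing in for the clinically observed hinge variants within the
lateral safe zone.  Their positions are configuration, not anatomy: no
published coordinates exist, so the defaults are illustrative and every axis
is overridable via explicit L-point landmarks or :class:`HingeAxesConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Axis3D, Plane, RigidTransform, SurfaceMesh, unit

__all__ = [
    "REQUIRED_LANDMARKS",
    "LandmarkSet",
    "AnatomicalFrame",
    "HingeAxesConfig",
    "build_tibial_frame",
    "normalize_to_frame",
    "locate_m0",
    "build_cutting_plane",
    "build_hinge_axes",
]

REQUIRED_LANDMARKS = (
    "acl_insertion",
    "pcl_insertion",
    "distal_articular_center",
    "fibular_head",
    "medial_plateau_edge",
    "lateral_plateau_edge",
    "hip_center",
    "distal_tibia_center",
)

#: optional landmarks understood by the pipeline
OPTIONAL_LANDMARKS = ("m0", "l0", "l1", "l2", "l3")

_Z = np.array([0.0, 0.0, 1.0])
_Y = np.array([0.0, 1.0, 0.0])
_X = np.array([1.0, 0.0, 0.0])


@dataclass
class LandmarkSet:
    """Named anatomical points in millimetres plus the knee side.

    Unknown names are preserved; the required names must be present and
    finite.
    """

    points: dict[str, np.ndarray]
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        pts = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} is not finite")
            pts[name] = p
        missing = [n for n in REQUIRED_LANDMARKS if n not in pts]
        if missing:
            raise ValueError(f"missing required landmarks: {', '.join(missing)}")
        if np.allclose(pts["medial_plateau_edge"], pts["lateral_plateau_edge"]):
            raise ValueError("medial and lateral plateau edges coincide")
        self.points = pts

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def get(self, name: str, default=None):
        return self.points.get(name, default)

    def transform(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({k: T.apply(v) for k, v in self.points.items()}, self.side)

    def mirrored_to_right(self) -> "LandmarkSet":
        """Mirror a left knee about the sagittal plane (x -> -x)."""
        if self.side == "right":
            return self
        return LandmarkSet(
            {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in self.points.items()}, "right"
        )


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal frame: z proximal, y anterior, x lateral."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        for name in ("x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = self.basis
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("frame must be right-handed")

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix with the frame axes as columns (world coordinates)."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), _X, _Y, _Z)

    def world_to_frame(self) -> RigidTransform:
        """Rigid transform taking world coordinates into frame coordinates."""
        R = self.basis.T
        return RigidTransform(R, -R @ self.origin)

    def frame_to_world(self) -> RigidTransform:
        return self.world_to_frame().inverse()


def build_tibial_frame(lm: LandmarkSet) -> AnatomicalFrame:
    """Tibial anatomical frame from ACL/PCL insertions and the distal centre.

    origin = distal articular centre; z = towards the ACL/PCL midpoint;
    y = component of (ACL - PCL) orthogonal to z (anterior, since the ACL
    inserts anterior to the PCL); x = y x z (lateral for a right knee).
    """
    acl, pcl = lm["acl_insertion"], lm["pcl_insertion"]
    origin = lm["distal_articular_center"]
    z = unit(0.5 * (acl + pcl) - origin)
    ap = acl - pcl
    y_raw = ap - (ap @ z) * z
    if np.linalg.norm(y_raw) < 1e-9:
        raise ValueError("ACL-PCL direction is parallel to the long axis; frame undefined")
    y = unit(y_raw)
    x = np.cross(y, z)
    return AnatomicalFrame(origin, x, y, z)


def normalize_to_frame(mesh: SurfaceMesh, frame: AnatomicalFrame) -> SurfaceMesh:
    """Express mesh vertices in frame coordinates (spatial normalisation)."""
    T = frame.world_to_frame()
    out = mesh.copy()
    out.vertices = T.apply(out.vertices)
    return out


def locate_m0(lm: LandmarkSet, offset_mm: float = 35.0) -> np.ndarray:
    """Medial cut entry: ``offset_mm`` inferior to the medial plateau edge.

    Requires frame-normalised landmarks (z is the proximal direction).
    """
    if offset_mm < 0:
        raise ValueError("offset must be non-negative")
    return lm["medial_plateau_edge"] - offset_mm * _Z


def build_cutting_plane(lm: LandmarkSet, m0_offset_mm: float = 35.0) -> Plane:
    """Osteotomy plane through M0 and the fibular head, parallel to y.

    The plane is the horizontal plane rotated about the anteroposterior axis
    until it contains both points; its normal therefore has zero y-component
    and is sign-corrected to point proximally (normal . z > 0), which makes
    "above the plane" mean "proximal fragment" downstream.
    """
    m0 = lm.get("m0")
    if m0 is None:
        m0 = locate_m0(lm, m0_offset_mm)
    fh = lm["fibular_head"]
    v = fh - m0
    n = np.cross(_Y, v)  # = (v_z, 0, -v_x): automatically y-free
    if np.linalg.norm(n) < 1e-9:
        raise ValueError("fibular head and M0 are vertically aligned; plane undefined")
    n = unit(n)
    if n @ _Z < 0:
        n = -n
    if abs(n @ _Z) < 1e-12:
        raise ValueError("degenerate vertical cutting plane")
    return Plane(m0, n)


@dataclass(frozen=True)
class HingeAxesConfig:
    """Placement of the default hinge axes near the lateral cortex.

    lateral_inset_mm: distance of the hinge base point medial to the lateral
    plateau edge (keeps the hinge inside the safe zone rather than on the
    cortex surface).  axis_spacing_mm: in-plane mediolateral separation of the
    two anteroposterior axes.  oblique_*: in-plane offsets of L0/L3 defining
    the oblique third axis.  plane_tol_mm / reject_mm: explicit L-points
    farther than plane_tol_mm from the plane are projected with a warning and
    rejected beyond reject_mm.
    """

    lateral_inset_mm: float = 8.0
    axis_spacing_mm: float = 10.0
    oblique_l0_offset: tuple[float, float] = (-12.0, -6.0)  # (anterior u, lateral w)
    oblique_l3_offset: tuple[float, float] = (12.0, 0.0)
    plane_tol_mm: float = 2.0
    reject_mm: float = 10.0


def _project_onto_plane_vertical(plane: Plane, x: float, y: float) -> np.ndarray:
    """Point of the plane above/below (x, y) (plane normal has n_z > 0)."""
    p, n = plane.point, plane.normal
    z = p[2] - (n[0] * (x - p[0]) + n[1] * (y - p[1])) / n[2]
    return np.array([x, y, z])


def _plane_point(plane: Plane, point: np.ndarray, cfg: HingeAxesConfig, name: str) -> np.ndarray:
    d = float(plane.signed_distance(point)[0])
    if abs(d) > cfg.reject_mm:
        raise ValueError(f"landmark {name} is {abs(d):.1f} mm from the cutting plane")
    if abs(d) > cfg.plane_tol_mm:
        warnings.warn(
            f"landmark {name} is {abs(d):.2f} mm off the cutting plane; projecting",
            stacklevel=3,
        )
    return point - d * plane.normal


def build_hinge_axes(
    plane: Plane,
    lm: LandmarkSet,
    config: HingeAxesConfig | None = None,
) -> list[Axis3D]:
    """Three hinge axes in the cutting plane (axis1, axis2, axis3).

    axis1/axis2 are anteroposterior in-plane lines through L1/L2; axis3 runs
    through L0 and L3 (oblique).  When the landmark set carries explicit
    l0..l3 points they are used (projected onto the plane within tolerance);
    otherwise illustrative defaults are derived from the lateral plateau
    edge: a hinge base point inset medially from the lateral cortex at plane
    level, with the second axis ``axis_spacing_mm`` medial to the first.
    Every returned axis satisfies the in-plane contract: its point lies on
    the plane and its direction is orthogonal to the plane normal.
    """
    cfg = config or HingeAxesConfig()
    n = plane.normal
    # in-plane anteroposterior and lateral directions
    u = unit(_Y - (_Y @ n) * n)
    w = unit(_X - (_X @ n) * n)

    lat = lm["lateral_plateau_edge"]
    med = lm["medial_plateau_edge"]
    y_mid = 0.5 * (lat[1] + med[1])
    base = _project_onto_plane_vertical(plane, lat[0] - cfg.lateral_inset_mm, y_mid)

    l1 = lm.get("l1")
    l1 = base if l1 is None else _plane_point(plane, l1, cfg, "l1")
    l2 = lm.get("l2")
    l2 = base - cfg.axis_spacing_mm * w if l2 is None else _plane_point(plane, l2, cfg, "l2")
    l0 = lm.get("l0")
    if l0 is None:
        l0 = base + cfg.oblique_l0_offset[0] * u + cfg.oblique_l0_offset[1] * w
    else:
        l0 = _plane_point(plane, l0, cfg, "l0")
    l3 = lm.get("l3")
    if l3 is None:
        l3 = base + cfg.oblique_l3_offset[0] * u + cfg.oblique_l3_offset[1] * w
    else:
        l3 = _plane_point(plane, l3, cfg, "l3")

    axes = [
        Axis3D.through(l1, u, "axis1"),
        Axis3D.through(l2, u, "axis2"),
        Axis3D.through(l0, l3 - l0, "axis3"),
    ]
    for ax in axes:
        if abs(ax.direction @ n) > 1e-9:
            raise ValueError(f"hinge {ax.label} direction not in the cutting plane")
        if abs(float(plane.signed_distance(ax.point)[0])) > 1e-6:
            raise ValueError(f"hinge {ax.label} point not on the cutting plane")
    return axes
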