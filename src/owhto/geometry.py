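"""Rigid-geometry primitives: meshes, planes, axes, and rigid transforms.

All coordinates are millimetres in a right-handed frame; angles are degrees at
every public interface (radians are used only internally).  These types carry
the whole pipeline: the osteotomy plane is a :class:`Plane`, a hinge is an
:class:`Axis3D`, and one simulated surgery is a rotation built by
:func:`rotation_about_axis` applied to the proximal vertex set of a
:class:`SurfaceMesh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SurfaceMesh",
    "Plane",
    "Axis3D",
    "RigidTransform",
    "rotation_about_axis",
    "apply_transform",
    "classify_by_plane",
    "crop_mesh",
    "mirror_mesh",
]

_UNIT_TOL = 1e-9


def _as_point(p, name: str = "point") -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} must be finite, got {p}")
    return p


def _as_unit(v, tol: float = _UNIT_TOL, name: str = "direction") -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or abs(n - 1.0) > tol:
        raise ValueError(f"{name} must be a unit vector (|v|={n!r})")
    return v / n


def unit(v) -> np.ndarray:
    """Normalise a 3-vector, rejecting near-zero input."""
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a (near-)zero vector")
    return v / n


@dataclass
class SurfaceMesh:
    """Triangle surface mesh of a bone in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples; each face must have three distinct indices in
        ``[0, n)``.  An empty face list is allowed (a vertex cloud, e.g. a
        degenerate crop result) but is flagged by :func:`crop_mesh`.
    vertex_labels : (n,) str array, optional
        Per-vertex component labels (e.g. ``"tibia"`` / ``"fibula"``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face (repeated vertex index)")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels)
            if self.vertex_labels.shape != (len(self.vertices),):
                raise ValueError("vertex_labels must have one entry per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        labels = None if self.vertex_labels is None else self.vertex_labels.copy()
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), labels)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "normal", _as_unit(self.normal, name="normal"))

    @classmethod
    def from_point_normal(cls, point, normal) -> "Plane":
        """Build a plane, normalising ``normal`` (must be nonzero)."""
        return cls(_as_point(point), unit(normal))

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def project(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d = self.signed_distance(pts)
        return np.atleast_2d(pts) - np.outer(d, self.normal)


@dataclass(frozen=True)
class Axis3D:
    """Line in space: a point on the line, a unit direction, and a label."""

    point: np.ndarray
    direction: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", _as_point(self.point))
        object.__setattr__(self, "direction", _as_unit(self.direction))

    @classmethod
    def through(cls, point, direction, label: str = "") -> "Axis3D":
        """Build an axis, normalising ``direction`` (must be nonzero)."""
        return cls(_as_point(point), unit(direction), label)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform entries must be finite")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees, recovered from the matrix."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )


def rotation_about_axis(axis: Axis3D, theta_deg: float) -> RigidTransform:
    """Rigid rotation by ``theta_deg`` degrees about an arbitrary axis.

    Implements v -> p + R(theta) (v - p) with p = ``axis.point`` and R the
    axis-angle (Rodrigues) rotation about ``axis.direction``.  Composing with
    the opposite angle yields the identity.
    """
    if not np.isfinite(theta_deg):
        raise ValueError("theta must be finite")
    R = Rotation.from_rotvec(np.radians(theta_deg) * axis.direction).as_matrix()
    p = axis.point
    return RigidTransform(R, p - R @ p)


def apply_transform(mesh: SurfaceMesh, transform: RigidTransform, vertex_subset=None) -> SurfaceMesh:
    """Apply a rigid transform to all vertices or to an index subset.

    Vertices outside the subset are bit-identical to the input; faces and
    labels are unchanged.
    """
    out = mesh.copy()
    if vertex_subset is None:
        out.vertices = transform.apply(out.vertices)
        return out
    idx = np.asarray(vertex_subset, dtype=np.int64).reshape(-1)
    if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
        raise IndexError("vertex_subset index out of range")
    out.vertices[idx] = transform.apply(out.vertices[idx])
    return out


def classify_by_plane(mesh: SurfaceMesh, plane: Plane) -> tuple[np.ndarray, np.ndarray]:
    """Partition vertex indices into (proximal, distal) sets by plane side.

    A vertex is proximal iff its signed distance to the plane is strictly
    positive; ties (exactly on the plane) go distal, so hinge vertices stay
    with the fixed fragment.  The partition is exhaustive and disjoint.
    """
    s = plane.signed_distance(mesh.vertices)
    proximal = np.flatnonzero(s > 0)
    distal = np.flatnonzero(s <= 0)
    if proximal.size == 0:
        warnings.warn("no vertices proximal to the plane", stacklevel=2)
    return proximal, distal


def crop_mesh(mesh: SurfaceMesh, keep) -> SurfaceMesh:
    """Keep a vertex subset and the faces entirely supported by it.

    Vertex indices are remapped consistently.  A result with zero faces (a
    bare vertex cloud) is allowed but flagged with a warning.
    """
    keep = np.unique(np.asarray(keep, dtype=np.int64).reshape(-1))
    if keep.size == 0:
        raise ValueError("crop would remove every vertex")
    if keep.min() < 0 or keep.max() >= mesh.n_vertices:
        raise IndexError("keep index out of range")
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    if mesh.n_faces:
        mask = np.all(remap[mesh.faces] >= 0, axis=1)
        faces = remap[mesh.faces[mask]]
    else:
        faces = np.zeros((0, 3), dtype=np.int64)
    if len(faces) == 0:
        warnings.warn("crop produced a mesh with zero faces (vertex cloud)", stacklevel=2)
    labels = None if mesh.vertex_labels is None else mesh.vertex_labels[keep]
    return SurfaceMesh(mesh.vertices[keep], faces, labels)


def mirror_mesh(mesh: SurfaceMesh, axis: int = 0) -> SurfaceMesh:
    """Mirror a mesh about a coordinate plane (default sagittal, x -> -x).

    Face winding is reversed so outward normals stay outward.
    """
    out = mesh.copy()
    out.vertices[:, axis] *= -1.0
    if out.n_faces:
        out.faces = out.faces[:, ::-1].copy()
    return out
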