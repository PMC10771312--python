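"""Shared fixtures: coarse surrogate tibia, normalized planning context."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from owhto.anatomy import build_cutting_plane, build_hinge_axes, build_tibial_frame, normalize_to_frame
from owhto.geometry import SurfaceMesh
from owhto.synthetic import TibiaParams, generate_tibia


@pytest.fixture(autouse=True)
def _quiet_geometry_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def coarse_params() -> TibiaParams:
    # 3 mm edges: fast but fine enough for sub-degree geometry checks
    return TibiaParams(mesh_edge_length=3.0)


@pytest.fixture(scope="session")
def coarse_tibia(coarse_params):
    return generate_tibia(coarse_params)


@pytest.fixture(scope="session")
def planning(coarse_tibia):
    """Frame-normalised mesh, landmarks, cutting plane and hinge axes."""
    mesh0, lm0 = coarse_tibia
    frame = build_tibial_frame(lm0)
    mesh = normalize_to_frame(mesh0, frame)
    lm = lm0.transform(frame.world_to_frame())
    plane = build_cutting_plane(lm)
    axes = build_hinge_axes(plane, lm)
    return {"mesh": mesh, "lm": lm, "frame": frame, "plane": plane, "axes": axes}


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    """Axis-aligned unit cube at the origin (8 vertices, 12 faces)."""
    v = np.array(
        [[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0) for x in (0.0, 1.0)]
    )
    f = np.array(
        [
            [0, 2, 1], [1, 2, 3],
            [4, 5, 6], [5, 7, 6],
            [0, 1, 4], [1, 5, 4],
            [2, 6, 3], [3, 6, 7],
            [0, 4, 2], [2, 4, 6],
            [1, 3, 5], [3, 7, 5],
        ]
    )
    return SurfaceMesh(v, f)


def flat_grid(n: int, size: float, z: float) -> SurfaceMesh:
    """Square n x n vertex grid triangulated in the z = const plane."""
    xs = np.linspace(-size / 2, size / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([X.ravel(), Y.ravel(), np.full(n * n, z)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(v, np.array(faces))
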