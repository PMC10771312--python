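"""Mechanical-line alignment and Fujisawa-point selection of simulations.

Limb alignment is quantified in the frontal (x-z) projection by where the
mechanical line — hip joint centre to centre of the distal tibia — crosses
the tibial plateau, expressed as a percentage of the medial(0%) to
lateral(100%) plateau width.  The classical valgus-correction target is the
Fujisawa point at 62.5%; simulations whose mechanical line crosses within an
acceptance band (default +-5%, i.e. 57.5%-67.5%, boundaries inclusive) are
selected as clinically acceptable candidates.

The hip centre and the plateau edges move with the proximal fragment (the
femur is assumed to keep its preoperative relation to the tibial plateau),
while the distal tibia centre stays fixed — this is what makes the crossing
percentage increase with the wedge-opening angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import LandmarkSet
from .simulate import SimulationModel

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "MechanicalLine",
    "mechanical_line",
    "plateau_crossing_pct",
    "evaluate_simulation",
    "select_acceptable",
    "arc_acceptable",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Fujisawa target percentage and the half-width of the acceptance band."""

    fujisawa_pct: float = 62.5
    tolerance_pct: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fujisawa_pct - self.tolerance_pct
                and self.fujisawa_pct + self.tolerance_pct < 100.0):
            raise ValueError("acceptance band must lie strictly inside (0, 100)%")

    @property
    def band(self) -> tuple[float, float]:
        return (self.fujisawa_pct - self.tolerance_pct, self.fujisawa_pct + self.tolerance_pct)


@dataclass(frozen=True)
class MechanicalLine:
    """Parametric line through the hip centre and the distal tibia centre."""

    hip: np.ndarray
    distal: np.ndarray

    def point_at(self, t: float) -> np.ndarray:
        return self.hip + t * (self.distal - self.hip)


@dataclass
class AlignmentResult:
    """Plateau-crossing percentage, acceptability, and the line endpoints."""

    crossing_pct: float
    acceptable: bool
    mechanical_line: MechanicalLine


def mechanical_line(hip_center, distal_tibia_center) -> MechanicalLine:
    hip = np.asarray(hip_center, dtype=float).reshape(3)
    distal = np.asarray(distal_tibia_center, dtype=float).reshape(3)
    if np.linalg.norm(hip - distal) < 1e-9:
        raise ValueError("hip centre and distal tibia centre coincide")
    return MechanicalLine(hip, distal)


def _frontal(p: np.ndarray) -> np.ndarray:
    """Project to the frontal plane: keep (x, z)."""
    return np.asarray([p[0], p[2]], dtype=float)


def plateau_crossing_pct(line: MechanicalLine, medial_edge, lateral_edge) -> float:
    """Where the mechanical line crosses the plateau, as a percentage.

    Intersects the frontal projections of the line and of the supporting line
    of the medial->lateral plateau segment; 0% at the medial edge, 100% at
    the lateral edge.  Values outside [0, 100] are valid (severe deformity)
    and reported as-is.
    """
    med = np.asarray(medial_edge, dtype=float).reshape(3)
    lat = np.asarray(lateral_edge, dtype=float).reshape(3)
    a, b = _frontal(line.hip), _frontal(line.distal)
    m, l = _frontal(med), _frontal(lat)
    if np.linalg.norm(l - m) < 1e-9:
        raise ValueError("plateau edges coincide in the frontal projection")
    # a + t(b-a) = m + s(l-m)
    A = np.column_stack([b - a, -(l - m)])
    det = np.linalg.det(A)
    if abs(det) < 1e-12 * max(np.linalg.norm(b - a), 1.0) * np.linalg.norm(l - m):
        raise ValueError("mechanical line is parallel to the plateau in the frontal projection")
    _, s = np.linalg.solve(A, m - a)
    return float(100.0 * s)


def _transformed_alignment_points(model: SimulationModel, lm: LandmarkSet):
    """Hip centre and plateau edges follow the proximal fragment; ankle is fixed."""
    T = model.transform
    hip = T.apply(lm["hip_center"])
    med = T.apply(lm["medial_plateau_edge"])
    lat = T.apply(lm["lateral_plateau_edge"])
    return hip, med, lat, lm["distal_tibia_center"]


def evaluate_simulation(
    model: SimulationModel, lm: LandmarkSet, cfg: AlignmentConfig | None = None
) -> AlignmentResult:
    """Crossing percentage of one simulated realignment and its acceptability.

    At theta = 0 the transform is the identity and the result is exactly the
    preoperative crossing.
    """
    cfg = cfg or AlignmentConfig()
    hip, med, lat, distal = _transformed_alignment_points(model, lm)
    line = mechanical_line(hip, distal)
    pct = plateau_crossing_pct(line, med, lat)
    lo, hi = cfg.band
    # inclusive boundaries, guarded against floating-point dust at the edges
    eps = 1e-9
    return AlignmentResult(pct, bool(lo - eps <= pct <= hi + eps), line)


def select_acceptable(
    models: list[SimulationModel], lm: LandmarkSet, cfg: AlignmentConfig | None = None
) -> list[tuple[SimulationModel, AlignmentResult]]:
    """Models whose mechanical line crosses within the acceptance band.

    An empty selection is a valid outcome and simply returns an empty list.
    """
    if not models:
        raise ValueError("no models to evaluate")
    cfg = cfg or AlignmentConfig()
    out = []
    for m in models:
        res = evaluate_simulation(m, lm, cfg)
        if res.acceptable:
            out.append((m, res))
    return out


def arc_acceptable(
    model: SimulationModel, lm: LandmarkSet, cfg: AlignmentConfig | None = None
) -> bool:
    """Acceptability via the hip-centred arc construction.

    The arc through the band-endpoint plateau points, centred on the hip
    joint centre, bounds an angular sector; the simulation is acceptable when
    the mechanical line leaves the hip within that sector.  Geometrically
    equivalent to the percentage band evaluated at the plateau level; kept as
    an independent route for validation.
    """
    cfg = cfg or AlignmentConfig()
    hip, med, lat, distal = _transformed_alignment_points(model, lm)
    line = mechanical_line(hip, distal)
    pct = plateau_crossing_pct(line, med, lat)

    m2, l2, h2 = _frontal(med), _frontal(lat), _frontal(hip)
    crossing = m2 + (pct / 100.0) * (l2 - m2)
    lo_pt = m2 + (cfg.band[0] / 100.0) * (l2 - m2)
    hi_pt = m2 + (cfg.band[1] / 100.0) * (l2 - m2)

    def ang(v):
        return np.arctan2(v[1], v[0])

    a_lo = 0.0
    a_hi = _wrap(ang(hi_pt - h2) - ang(lo_pt - h2))
    a_x = _wrap(ang(crossing - h2) - ang(lo_pt - h2))
    lo, hi = sorted((0.0, a_hi))
    return bool(lo <= a_x <= hi)


def _wrap(a: float) -> float:
    return float((a + np.pi) % (2.0 * np.pi) - np.pi)
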