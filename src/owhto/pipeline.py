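"""End-to-end run configuration and orchestration.

``run_pipeline`` ties the stages together: load mesh + landmarks (mirroring
left knees to the canonical right-knee frame), normalise to the tibial
anatomical frame, build the cutting plane and hinge axes, sweep the
simulation grid, optionally score it against a postoperative mesh, select
the Fujisawa-acceptable candidates, and write the artifacts (models,
distance-table CSV, selection JSON, run manifest).  Every artifact records
the configuration hash, so outputs with equal hashes came from identical
configurations; reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .alignment import AlignmentConfig, evaluate_simulation
from .anatomy import (
    HingeAxesConfig,
    build_cutting_plane,
    build_hinge_axes,
    build_tibial_frame,
    normalize_to_frame,
)
from .geometry import mirror_mesh
from .io import (
    load_mesh,
    read_landmarks,
    save_mesh,
    write_distance_table,
    write_selection,
)
from .registration import ICPOptions, grid_search
from .simulate import generate_grid

logger = logging.getLogger("owhto")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Fully explicit, serialisable run configuration.

    The theta sweep is (start, stop, step) in degrees, stop inclusive.
    """

    mesh_path: str
    landmarks_path: str
    out_dir: str
    postop_path: str | None = None
    theta_start: float = 1.0
    theta_stop: float = 20.0
    theta_step: float = 1.0
    m0_offset_mm: float = 35.0
    hinge: dict = field(default_factory=dict)
    icp: dict = field(default_factory=dict)
    distance_direction: str = "symmetric"
    fujisawa_pct: float = 62.5
    tolerance_pct: float = 5.0
    save_meshes: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def thetas(self) -> list[float]:
        if self.theta_step <= 0:
            raise ValueError("theta_step must be positive")
        out = []
        t = self.theta_start
        while t <= self.theta_stop + 1e-9:
            out.append(round(t, 9))
            t += self.theta_step
        return out

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _sanity_check_units(mesh) -> None:
    extent = (mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)).max()
    if not (30.0 <= extent <= 2000.0):
        raise ValueError(
            f"mesh extent {extent:.1f} looks wrong for a tibia in millimetres; "
            "check the input units"
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> (optional) compare -> select; write artifacts.

    Returns the run manifest (also written to ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.perf_counter()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    mesh = load_mesh(config.mesh_path)
    _sanity_check_units(mesh)
    lm = read_landmarks(config.landmarks_path)
    if lm.side == "left":
        logger.info("left knee: mirroring to canonical right-knee frame")
        mesh = mirror_mesh(mesh)
        lm = lm.mirrored_to_right()

    frame = build_tibial_frame(lm)
    mesh_n = normalize_to_frame(mesh, frame)
    lm_n = lm.transform(frame.world_to_frame())
    plane = build_cutting_plane(lm_n, config.m0_offset_mm)
    axes = build_hinge_axes(plane, lm_n, HingeAxesConfig(**config.hinge) if config.hinge else None)

    models = generate_grid(mesh_n, plane, axes, config.thetas())
    logger.info("simulated %d models (%d axes)", len(models), len(axes))

    chash = config.config_hash
    if config.save_meshes:
        model_dir = out_dir / "models"
        model_dir.mkdir(exist_ok=True)
        for m in models:
            stem = f"{m.plan.axis.label}_theta{m.plan.theta:g}"
            save_mesh(m.mesh, model_dir / f"{stem}.ply")
            sidecar = {
                "config_hash": chash,
                "axis": m.plan.axis.label,
                "theta_deg": float(m.plan.theta),
                "rotation": m.transform.rotation.tolist(),
                "translation": m.transform.translation.tolist(),
                "n_proximal_vertices": int(len(m.proximal_indices)),
                "proximal_indices": [int(i) for i in m.proximal_indices],
            }
            (model_dir / f"{stem}.json").write_text(json.dumps(sidecar) + "\n")

    table_path = None
    best = None
    if config.postop_path:
        postop = load_mesh(config.postop_path)
        _sanity_check_units(postop)
        postop_n = normalize_to_frame(postop, frame)
        icp_opts = ICPOptions(**config.icp) if config.icp else None
        table, best = grid_search(
            models,
            postop_n,
            plane,
            icp_opts,
            config.distance_direction,
            provenance={
                "config_hash": chash,
                "mesh": str(config.mesh_path),
                "postop": str(config.postop_path),
            },
        )
        table_path = out_dir / "distance_table.csv"
        write_distance_table(table, table_path)
        logger.info("best (axis, theta): %s", best)

    cfg_align = AlignmentConfig(config.fujisawa_pct, config.tolerance_pct)
    evaluated = [(m, evaluate_simulation(m, lm_n, cfg_align)) for m in models]
    write_selection(evaluated, out_dir / "selection.json", chash)

    manifest = {
        "config_hash": chash,
        "config": config.to_dict(),
        "version": __version__,
        "n_models": len(models),
        "axes": [a.label for a in axes],
        "best": list(best) if best else None,
        "n_acceptable": sum(1 for _, r in evaluated if r.acceptable),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
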