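"""Run configuration: YAML loading, validation and resolved-config dumps."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .imaging import EdgeParams
from .registration import OptimizerConfig
from .synthetic import SceneSpec

__all__ = ["RunConfig", "load_config", "validate_inputs"]

_PATH_KEYS = {
    "rig",
    "meshes",
    "frames_left",
    "frames_right",
    "landmarks",
    "init_poses",
    "output",
}


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    paths: dict = dataclasses.field(default_factory=dict)
    edge_params: EdgeParams = dataclasses.field(default_factory=EdgeParams)
    optimizer: OptimizerConfig = dataclasses.field(default_factory=OptimizerConfig)
    scene: SceneSpec = dataclasses.field(default_factory=SceneSpec)
    log_level: str = "INFO"
    seed: int = 0

    def dump(self, path) -> None:
        """Write the fully resolved configuration next to run outputs."""
        payload = {
            "paths": {k: str(v) for k, v in self.paths.items()},
            "edge_params": dataclasses.asdict(self.edge_params),
            "optimizer": dataclasses.asdict(self.optimizer),
            "scene": dataclasses.asdict(self.scene),
            "log_level": self.log_level,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(payload, default=str)), fh)


def _build_section(cls, payload: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in payload.items():
        coerced[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"paths", "edge_params", "optimizer", "scene", "log_level", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    paths = raw.get("paths", {})
    bad = set(paths) - _PATH_KEYS
    if bad:
        raise ValueError(f"unknown path keys: {sorted(bad)}")
    return RunConfig(
        paths=paths,
        edge_params=_build_section(EdgeParams, raw.get("edge_params", {}), "edge_params"),
        optimizer=_build_section(OptimizerConfig, raw.get("optimizer", {}), "optimizer"),
        scene=_build_section(SceneSpec, raw.get("scene", {}), "scene"),
        log_level=raw.get("log_level", "INFO"),
        seed=int(raw.get("seed", 0)),
    )


def validate_inputs(config: RunConfig) -> list[str]:
    """Sanity-check the files a run will consume; returns problem strings."""
    import imageio.v3 as iio
    import numpy as np

    from .bone_model import load_mesh
    from .calibration import load_rig

    problems: list[str] = []
    paths = {k: Path(v) for k, v in config.paths.items()}
    rig = None
    if "rig" in paths:
        if not paths["rig"].exists():
            problems.append(f"rig file missing: {paths['rig']}")
        else:
            rig = load_rig(paths["rig"])
    n_frames = {}
    for key, vid in (("frames_left", "L"), ("frames_right", "R")):
        if key not in paths:
            continue
        files = sorted(paths[key].glob("*.png")) + sorted(paths[key].glob("*.tif*"))
        n_frames[vid] = len(files)
        if not files:
            problems.append(f"no frames found in {paths[key]}")
        elif rig is not None:
            img = iio.imread(files[0])
            model = rig.views[vid]
            if img.shape[:2] != (model.image_height, model.image_width):
                problems.append(
                    f"view {vid}: image {img.shape[:2]} does not match rig "
                    f"({model.image_height}, {model.image_width})"
                )
    if len(n_frames) == 2 and n_frames["L"] != n_frames["R"]:
        problems.append(
            f"frame count mismatch: L has {n_frames['L']}, R has {n_frames['R']}"
        )
    if "meshes" in paths:
        for mf in sorted(Path(paths["meshes"]).glob("*.ply")) + sorted(
            Path(paths["meshes"]).glob("*.stl")
        ):
            mesh = load_mesh(mf)
            extent = np.ptp(mesh.vertices, axis=0).max()
            if extent > 1e4:
                problems.append(
                    f"mesh {mf.name}: extent {extent:.0f} suggests wrong units "
                    "(expected mm)"
                )
    return problems
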