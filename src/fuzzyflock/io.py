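"""Run configuration, serialization and reproducibility plumbing.

Formats: run configs as JSON or TOML, rule-base pools as JSON, trajectories
and metrics as CSV, summaries as JSON. Every artifact-producing run writes a
manifest (seed, config hash, library versions) so results are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .evolution import EvolutionConfig, RuleBasePool
from .fuzzy import rulebase_from_dict, rulebase_to_dict
from .metrics import ValidationConfig
from .scenarios import ScriptedScene
from .world import World, WorldConfig

__all__ = [
    "RunConfig",
    "load_run_config",
    "dump_run_config",
    "config_hash",
    "save_pool",
    "load_pool",
    "write_manifest",
    "trajectory_frame",
    "write_trajectory",
    "read_trajectory",
    "scene_to_trajectory",
    "trajectory_to_scene",
    "write_events",
]

TRAJECTORY_COLUMNS = ["step", "agent_id", "kind", "tactic",
                      "x", "y", "heading", "energy"]


@dataclass
class RunConfig:
    """World + evolution + validation parameters plus run plumbing. The
    defaults reproduce the published parameter tables exactly."""

    world: WorldConfig = field(default_factory=WorldConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    seed: int = 0
    sample_interval: int = 500
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        return {
            "world": dataclasses.asdict(self.world),
            "evolution": dataclasses.asdict(self.evolution),
            "validation": dataclasses.asdict(self.validation),
            "seed": self.seed,
            "sample_interval": self.sample_interval,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, section):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(section) - names
            if unknown:
                raise ValueError(f"unknown {klass.__name__} fields: {sorted(unknown)}")
            return klass(**section)

        return cls(
            world=build(WorldConfig, data.get("world", {})),
            evolution=build(EvolutionConfig, data.get("evolution", {})),
            validation=build(ValidationConfig, data.get("validation", {})),
            seed=int(data.get("seed", 0)),
            sample_interval=int(data.get("sample_interval", 500)),
            out_dir=str(data.get("out_dir", "runs")),
        )


def load_run_config(path: Union[str, Path]) -> RunConfig:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return RunConfig.from_dict(data)


def dump_run_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2))


def config_hash(cfg: RunConfig) -> str:
    """Hash of the scientific configuration (output paths excluded)."""
    data = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    canon = json.dumps(data, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: Union[str, Path], cfg: RunConfig, **extra) -> None:
    from . import __version__

    manifest = {"config_hash": config_hash(cfg), "seed": cfg.seed,
                "fuzzyflock": __version__, "numpy": np.__version__,
                "pandas": pd.__version__} | extra
    Path(path).write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Rule-base pools
# ---------------------------------------------------------------------------

def save_pool(pool: RuleBasePool, path: Union[str, Path], **meta) -> None:
    data = {"meta": {"seed": pool.seed, "steps": pool.steps,
                     "n_rulebases": len(pool)} | meta,
            "rulebases": [rulebase_to_dict(rb) for rb in pool.rulebases]}
    Path(path).write_text(json.dumps(data))


def load_pool(path: Union[str, Path]) -> RuleBasePool:
    data = json.loads(Path(path).read_text())
    rbs = [rulebase_from_dict(rec) for rec in data["rulebases"]]
    meta = data.get("meta", {})
    return RuleBasePool(rbs, seed=meta.get("seed"), steps=meta.get("steps"))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def trajectory_frame(world: World) -> pd.DataFrame:
    """One row per agent for the world's current step."""
    rows = []
    for i in range(world.cfg.n_prey):
        rows.append({"step": world.step_count, "agent_id": int(world.prey_uid[i]),
                     "kind": "prey", "tactic": "",
                     "x": float(world.prey_pos[i, 0]), "y": float(world.prey_pos[i, 1]),
                     "heading": float(world.prey_heading[i]),
                     "energy": float(world.prey_energy[i])})
    for p in world.predators:
        if p.on_world:
            rows.append({"step": world.step_count, "agent_id": -1 - p.id,
                         "kind": "predator", "tactic": p.tactic,
                         "x": float(p.position[0]), "y": float(p.position[1]),
                         "heading": float(p.heading), "energy": float("nan")})
    return pd.DataFrame.from_records(rows, columns=TRAJECTORY_COLUMNS)


def write_trajectory(frames: Union[pd.DataFrame, list], path: Union[str, Path]) -> None:
    df = pd.concat(frames, ignore_index=True) if isinstance(frames, list) else frames
    df.to_csv(path, index=False)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tactic": str}, keep_default_na=False,
                       na_values={"energy": [""]})


def scene_to_trajectory(scene: ScriptedScene, step: int = 0) -> pd.DataFrame:
    """Emit a scripted scene in the simulator's trajectory CSV dialect."""
    rows = [{"step": step, "agent_id": i, "kind": "prey", "tactic": "",
             "x": float(x), "y": float(y), "heading": float(h),
             "energy": float("nan")}
            for i, ((x, y), h) in enumerate(zip(scene.positions, scene.headings))]
    if scene.predator_position is not None:
        rows.append({"step": step, "agent_id": -1, "kind": "predator", "tactic": "",
                     "x": float(scene.predator_position[0]),
                     "y": float(scene.predator_position[1]),
                     "heading": float(scene.predator_heading or 0.0),
                     "energy": float("nan")})
    return pd.DataFrame.from_records(rows, columns=TRAJECTORY_COLUMNS)


def trajectory_to_scene(df: pd.DataFrame, step: Optional[int] = None) -> ScriptedScene:
    if step is None:
        step = int(df["step"].min())
    sub = df[df["step"] == step]
    prey = sub[sub["kind"] == "prey"]
    pred = sub[sub["kind"] == "predator"]
    return ScriptedScene(
        prey[["x", "y"]].to_numpy(float), prey["heading"].to_numpy(float),
        predator_position=(pred[["x", "y"]].to_numpy(float)[0] if len(pred) else None),
        predator_heading=(float(pred["heading"].iloc[0]) if len(pred) else None))


def write_events(world: World, path: Union[str, Path]) -> None:
    rows = [{"step": s, "event": e,
             "agent_id": ids[0] if ids else "",
             "other_id": ids[1] if len(ids) > 1 else ""}
            for (s, e, *ids) in world.events]
    pd.DataFrame.from_records(
        rows, columns=["step", "event", "agent_id", "other_id"]).to_csv(path, index=False)
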