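"""Order parameters, grouping, collective-state classification and the
validation protocol.

A group's *polarization* p is the norm of its mean unit direction vector
(1 = perfectly aligned); its *rotation* m is the magnitude of the mean cross
product of the unit centroid-to-agent vector with the unit velocity
(1 = perfect mill). A group is in the polar state (P) when p > 0.65 and
m < 0.35, milling (M) when p < 0.35 and m > 0.65, swarming (S) when both are
below 0.35, and otherwise in transition (T).

Groups are the connected components of the mutual-proximity graph (edge
between prey closer than the perception distance); singletons are stragglers
and are excluded from local-scale analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .evolution import RuleBasePool
from .fuzzy import FuzzyRuleBase
from .world import World, WorldConfig

__all__ = [
    "GroupPartition",
    "ValidationConfig",
    "polarization",
    "rotation",
    "find_groups",
    "classify_state",
    "local_density",
    "state_time_proportions",
    "bootstrap_ci",
    "run_validation",
    "group_size_experiment",
    "behaviour_class",
]

STATES = ("P", "M", "S", "T")


@dataclass(frozen=True)
class GroupPartition:
    """Groups (size >= 2) plus stragglers; together they partition the prey."""

    groups: tuple[tuple[int, ...], ...]
    stragglers: tuple[int, ...]


@dataclass
class ValidationConfig:
    """Protocol for evaluating an evolved pool: scatter the prey, let the
    scene stabilise, record a predator-free window, then introduce one
    predator and record again."""

    replicates: int = 20
    stabilisation: int = 900
    predator_introduction: int = 1800
    total: int = 3600
    bootstrap_resamples: int = 10_000

    def __post_init__(self):
        if not (self.stabilisation < self.predator_introduction < self.total):
            raise ValueError("requires stabilisation < predator_introduction < total")


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

def _units(headings) -> np.ndarray:
    h = np.radians(np.asarray(headings, dtype=float))
    return np.stack([np.cos(h), np.sin(h)], axis=-1)


def polarization(headings) -> float:
    """Norm of the mean unit direction vector; in [0, 1]."""
    v = _units(headings)
    if v.ndim == 1:
        v = v[None, :]
    return float(np.hypot(*v.mean(axis=0)))


def rotation(positions, headings) -> float:
    """|mean of c_i x v_i| where c_i is the unit vector from the group
    centroid to agent i; agents exactly on the centroid contribute 0."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    v = _units(headings)
    if v.ndim == 1:
        v = v[None, :]
    c = pos - pos.mean(axis=0)
    norm = np.hypot(c[:, 0], c[:, 1])
    safe = np.where(norm > 0.0, norm, 1.0)
    c = c / safe[:, None]
    c[norm == 0.0] = 0.0
    cross = c[:, 0] * v[:, 1] - c[:, 1] * v[:, 0]
    return float(abs(cross.mean()))


def find_groups(positions, perception_distance: float) -> GroupPartition:
    """Connected components of the graph linking prey strictly closer than
    the perception distance; singleton components become stragglers."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n == 0:
        return GroupPartition((), ())
    d = squareform(pdist(pos)) if n > 1 else np.zeros((1, 1))
    adj = csr_matrix((d < perception_distance) & ~np.eye(n, dtype=bool))
    k, labels = connected_components(adj, directed=False)
    groups, stragglers = [], []
    for comp in range(k):
        members = tuple(int(i) for i in np.flatnonzero(labels == comp))
        if len(members) >= 2:
            groups.append(members)
        else:
            stragglers.extend(members)
    return GroupPartition(tuple(groups), tuple(stragglers))


def classify_state(p: float, m: float) -> str:
    """Threshold classification of (polarization, rotation) into P/M/S/T."""
    if p > 0.65 and m < 0.35:
        return "P"
    if p < 0.35 and m > 0.65:
        return "M"
    if p < 0.35 and m < 0.35:
        return "S"
    return "T"


def local_density(positions, radius: float) -> tuple[np.ndarray, float]:
    """Per-agent count of conspecifics strictly within ``radius`` and the
    population mean of those counts."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if n < 2:
        return np.zeros(n, dtype=int), 0.0
    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    counts = (d < radius).sum(axis=1)
    return counts, float(counts.mean())


def state_time_proportions(per_step_labels: Iterable[Sequence[str]]) -> dict[str, float]:
    """Time-in-state allocation: each step's unit weight is split equally
    across that step's groups; steps with no groups contribute nothing."""
    weight = dict.fromkeys(STATES, 0.0)
    counted = 0.0
    for labels in per_step_labels:
        if not labels:
            continue
        counted += 1.0
        share = 1.0 / len(labels)
        for s in labels:
            weight[s] += share
    if counted == 0:
        raise ValueError("no step with at least one group")
    return {s: w / counted for s, w in weight.items()}


def bootstrap_ci(samples, rng: np.random.Generator,
                 n_resamples: int = 10_000,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    idx = rng.integers(0, x.size, size=(n_resamples, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def behaviour_class(proportions: dict[str, float]) -> str:
    """Argmax state-time class: P, M or S, or D (dynamic) when transition
    dominates."""
    top = max(proportions, key=lambda s: proportions[s])
    return "D" if top == "T" else top


# ---------------------------------------------------------------------------
# Validation protocol
# ---------------------------------------------------------------------------

def _pool_hook(pool: RuleBasePool):
    def hook(world: World, dead_slot: int, survivors) -> FuzzyRuleBase:
        return pool.rulebases[int(world.rng.integers(len(pool.rulebases)))]
    return hook


def measure_step(world: World) -> tuple[list[dict], list[str]]:
    """Per-group and global metric rows for the current world state."""
    pos, head = world.prey_pos, world.prey_heading
    cfg = world.cfg
    part = find_groups(pos, cfg.prey_perception)
    _, mean_density = local_density(pos, cfg.prey_perception)
    rows, labels = [], []
    base = {"step": world.step_count, "n_groups": len(part.groups),
            "mean_local_density": mean_density}
    for gid, members in enumerate(part.groups):
        m = list(members)
        p = polarization(head[m])
        r = rotation(pos[m], head[m])
        s = classify_state(p, r)
        labels.append(s)
        rows.append(base | {"group_id": str(gid), "n_members": len(m),
                            "polarization": p, "rotation": r, "state": s})
    gp = polarization(head)
    gr = rotation(pos, head)
    rows.append(base | {"group_id": "GLOBAL", "n_members": len(pos),
                        "polarization": gp, "rotation": gr,
                        "state": classify_state(gp, gr)})
    return rows, labels


def run_validation(pool: RuleBasePool, cfg: ValidationConfig,
                   world_cfg: Optional[WorldConfig] = None,
                   rng: Optional[np.random.Generator] = None,
                   predator_tactic: Optional[str] = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Evaluate an evolved pool over ``cfg.replicates`` replicates.

    Evolution is disabled: dead or captured prey are replaced by agents whose
    rule base is drawn uniformly from the pool. Each replicate scatters
    ``n_prey`` agents on the spawn disc, runs a stabilisation period, records
    metrics over the predator-free window, introduces one predator at the
    configured step and keeps recording to the end. Returns the per-step
    metric table and a summary (means, bootstrap CIs, state-time proportions,
    behaviour class) per phase.
    """
    from .world import TACTICS

    base_cfg = world_cfg or WorldConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    hook = _pool_hook(pool)
    all_rows: list[dict] = []
    labels_free: list[list[str]] = []
    labels_pred: list[list[str]] = []

    for rep in range(cfg.replicates):
        tactic = predator_tactic or TACTICS[int(rng.integers(len(TACTICS)))]
        wcfg = WorldConfig(**{**base_cfg.__dict__, "n_predators": 1})
        rb = [pool.rulebases[int(rng.integers(len(pool.rulebases)))]
              for _ in range(wcfg.n_prey)]
        world = World(wcfg, rb, rng=rng)
        world.scatter_prey()
        pred = world.predators[0]
        pred.tactic = tactic
        pred.countdown = cfg.predator_introduction  # enters exactly then

        for _ in range(cfg.total):
            world.step(hook)
            if world.step_count > cfg.stabilisation:
                rows, labels = measure_step(world)
                phase = ("predator" if world.step_count > cfg.predator_introduction
                         else "free")
                for r in rows:
                    r["replicate"] = rep
                    r["phase"] = phase
                all_rows.extend(rows)
                (labels_pred if phase == "predator" else labels_free).append(labels)

    table = pd.DataFrame.from_records(all_rows)
    summary = {"replicates": cfg.replicates, "phases": {}}
    brng = np.random.default_rng(rng.integers(2**31))
    for phase, labels in (("free", labels_free), ("predator", labels_pred)):
        sub = table[(table["phase"] == phase) & (table["group_id"] == "GLOBAL")]
        dens = sub.groupby("replicate")["mean_local_density"].mean().to_numpy()
        ngrp = sub.groupby("replicate")["n_groups"].mean().to_numpy()
        props = state_time_proportions(labels) if any(labels) else dict.fromkeys(STATES, 0.0)
        summary["phases"][phase] = {
            "mean_local_density": float(dens.mean()),
            "local_density_ci": bootstrap_ci(dens, brng, cfg.bootstrap_resamples),
            "mean_n_groups": float(ngrp.mean()),
            "n_groups_ci": bootstrap_ci(ngrp, brng, cfg.bootstrap_resamples),
            "state_time_proportions": props,
            "behaviour_class": behaviour_class(props) if any(labels) else None,
        }
    return table, summary


def group_size_experiment(pool: RuleBasePool,
                          sizes: Sequence[int] = (30, 70, 150, 300),
                          replicates: int = 20,
                          record_window: tuple[int, int] = (900, 1800),
                          world_cfg: Optional[WorldConfig] = None,
                          rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Group-size sweep: per size and replicate, scatter that many agents
    with pool-sampled rule bases, no predators, and record the global
    (polarization, rotation) pair over the recording window."""
    base_cfg = world_cfg or WorldConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    hook = _pool_hook(pool)
    rows = []
    start, stop = record_window
    for size in sizes:
        for rep in range(replicates):
            wcfg = WorldConfig(**{**base_cfg.__dict__,
                                  "n_prey": int(size), "n_predators": 0})
            rb = [pool.rulebases[int(rng.integers(len(pool.rulebases)))]
                  for _ in range(size)]
            world = World(wcfg, rb, rng=rng)
            world.scatter_prey()
            for _ in range(stop):
                world.step(hook)
                if world.step_count > start:
                    rows.append({"size": size, "replicate": rep,
                                 "step": world.step_count,
                                 "polarization": polarization(world.prey_heading),
                                 "rotation": rotation(world.prey_pos,
                                                      world.prey_heading)})
    return pd.DataFrame.from_records(rows)
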