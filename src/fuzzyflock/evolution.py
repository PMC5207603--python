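"""Open-ended, steady-state genetic evolution of prey rule bases.

Each prey agent's chromosome is its whole rule base (Pittsburgh approach)
with variable-length (messy) coding. There are no generations: whenever a
prey dies — caught, starved through collisions, or worn down by wandering —
it is replaced immediately by an offspring of two fitness-proportionally
selected live agents, where fitness is the agent's current energy. The
offspring's rule base is built by choosing a random length and sampling
rules without replacement from the joint multiset of the parents' rules,
followed (with small probability) by an add-random-rules or
remove-existing-rules mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .fuzzy import (
    DATA_BASE,
    INPUT_VARIABLE_NAMES,
    MAX_ANTECEDENTS,
    MAX_RULES,
    OUTPUT_VARIABLE,
    FuzzyRule,
    FuzzyRuleBase,
)
from .world import World, WorldConfig

__all__ = [
    "EvolutionConfig",
    "RuleBasePool",
    "random_rule",
    "random_rulebase",
    "select_parents",
    "crossover",
    "mutate",
    "make_genetic_hook",
    "run_evolution",
]


@dataclass
class EvolutionConfig:
    """Evolutionary process parameters."""

    total_steps: int = 10_000_000
    rule_base_upper_bound: int = MAX_RULES
    antecedents_upper_bound: int = MAX_ANTECEDENTS
    mutation_probability: float = 0.02
    add_rules_upper_bound: int = 3
    remove_rules_upper_bound: int = 3
    crossover_with_replacement: bool = False
    sample_interval: int = 500  # metric-log cadence (steps)
    seed: int = 0

    def __post_init__(self):
        if min(self.rule_base_upper_bound, self.antecedents_upper_bound,
               self.add_rules_upper_bound, self.remove_rules_upper_bound,
               self.total_steps) <= 0:
            raise ValueError("bounds must be positive")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")


@dataclass
class RuleBasePool:
    """End-of-run snapshot: the rule bases of the currently-live prey."""

    rulebases: list[FuzzyRuleBase]
    seed: Optional[int] = None
    steps: Optional[int] = None

    def __len__(self) -> int:
        return len(self.rulebases)


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------

def random_rule(rng: np.random.Generator,
                max_antecedents: int = MAX_ANTECEDENTS) -> FuzzyRule:
    """A fully random rule: antecedent count uniform in [1, max], variables
    sampled uniformly without replacement, values and consequent uniform."""
    k = int(rng.integers(1, max_antecedents + 1))
    vars_ = rng.choice(len(INPUT_VARIABLE_NAMES), size=k, replace=False)
    ants = []
    for vi in vars_:
        name = INPUT_VARIABLE_NAMES[int(vi)]
        values = DATA_BASE[name].value_names
        ants.append((name, values[int(rng.integers(len(values)))]))
    out_values = OUTPUT_VARIABLE.value_names
    return FuzzyRule(tuple(ants), out_values[int(rng.integers(len(out_values)))])


def random_rulebase(rng: np.random.Generator,
                    max_rules: int = MAX_RULES,
                    max_antecedents: int = MAX_ANTECEDENTS) -> FuzzyRuleBase:
    """Random behaviour: length uniform in [1, max_rules], rules i.i.d."""
    n = int(rng.integers(1, max_rules + 1))
    return FuzzyRuleBase(tuple(random_rule(rng, max_antecedents) for _ in range(n)))


def select_parents(energies: np.ndarray, rng: np.random.Generator) -> tuple[int, int]:
    """Two distinct indices drawn proportionally to energy (fitness), without
    replacement."""
    e = np.asarray(energies, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two live prey to select parents")
    if np.any(e < 0):
        e = e - e.min()  # guard: weights must be non-negative
    total = e.sum()
    p = np.full(e.size, 1.0 / e.size) if total <= 0 else e / total
    a, b = rng.choice(e.size, size=2, replace=False, p=p)
    return int(a), int(b)


def crossover(pa: FuzzyRuleBase, pb: FuzzyRuleBase, rng: np.random.Generator,
              max_rules: int = MAX_RULES,
              with_replacement: bool = False) -> FuzzyRuleBase:
    """Joint-multiset crossover: offspring length uniform in
    [1, min(|pa|+|pb|, max_rules)], rules sampled uniformly (without
    replacement by default) from the concatenation of the parents' rules."""
    joint = tuple(pa.rules) + tuple(pb.rules)
    if not joint:
        raise ValueError("both parents must be non-empty")
    upper = min(len(joint), max_rules)
    n = int(rng.integers(1, upper + 1))
    picks = rng.choice(len(joint), size=n, replace=with_replacement)
    return FuzzyRuleBase(tuple(joint[int(i)] for i in picks))


def mutate(rb: FuzzyRuleBase, rng: np.random.Generator,
           cfg: Optional[EvolutionConfig] = None) -> FuzzyRuleBase:
    """With the configured probability, either add 1-3 fresh random rules
    (truncated at the rule-base upper bound) or remove 1-3 existing rules
    (never dropping below one rule); otherwise return the base unchanged."""
    cfg = cfg or EvolutionConfig()
    if rng.random() >= cfg.mutation_probability:
        return rb
    rules = list(rb.rules)
    if rng.random() < 0.5:  # add
        k = int(rng.integers(1, cfg.add_rules_upper_bound + 1))
        for _ in range(k):
            rules.append(random_rule(rng, cfg.antecedents_upper_bound))
        rules = rules[:cfg.rule_base_upper_bound]
    else:  # remove
        k = int(rng.integers(1, cfg.remove_rules_upper_bound + 1))
        k = min(k, max(len(rules) - 1, 0))
        for _ in range(k):
            rules.pop(int(rng.integers(len(rules))))
    return FuzzyRuleBase(tuple(rules))


def make_genetic_hook(cfg: EvolutionConfig):
    """Replacement hook: fitness-proportional parents -> crossover -> mutation.

    Parents are drawn from the agents that survived the current step.
    """
    def hook(world: World, dead_slot: int, survivors: np.ndarray) -> FuzzyRuleBase:
        ia, ib = select_parents(world.prey_energy[survivors], world.rng)
        pa = world.rulebases[int(survivors[ia])]
        pb = world.rulebases[int(survivors[ib])]
        child = crossover(pa, pb, world.rng, cfg.rule_base_upper_bound,
                          cfg.crossover_with_replacement)
        return mutate(child, world.rng, cfg)

    return hook


# ---------------------------------------------------------------------------
# Full evolutionary run
# ---------------------------------------------------------------------------

def run_evolution(world_cfg: WorldConfig, evo_cfg: EvolutionConfig,
                  rng: Optional[np.random.Generator] = None,
                  log_events: bool = False,
                  progress: Optional[Callable[[int], None]] = None,
                  ) -> tuple[RuleBasePool, pd.DataFrame, World]:
    """Evolve prey behaviour for ``total_steps`` update steps.

    The initial population carries random rule bases and is scattered
    uniformly on the spawn disc with uniform headings. Returns the end-state
    pool, a periodic metric log (local density, group count, global
    polarization/rotation) and the final world.
    """
    rng = rng if rng is not None else np.random.default_rng(evo_cfg.seed)
    rulebases = [random_rulebase(rng, evo_cfg.rule_base_upper_bound,
                                 evo_cfg.antecedents_upper_bound)
                 for _ in range(world_cfg.n_prey)]
    world = World(world_cfg, rulebases, rng=rng, log_events=log_events)
    world.scatter_prey()
    hook = make_genetic_hook(evo_cfg)

    records = [_metric_row(world)]
    for t in range(evo_cfg.total_steps):
        world.step(hook)
        if world.step_count % evo_cfg.sample_interval == 0:
            records.append(_metric_row(world))
        if progress is not None and world.step_count % 10_000 == 0:
            progress(world.step_count)
    log = pd.DataFrame.from_records(
        records, columns=["step", "mean_local_density", "n_groups",
                          "polarization", "rotation", "deaths", "captures"])
    pool = RuleBasePool(list(world.rulebases), seed=evo_cfg.seed,
                        steps=evo_cfg.total_steps)
    return pool, log, world


def _metric_row(world: World) -> tuple:
    from . import metrics as _metrics  # deferred: metrics imports RuleBasePool

    pos, head = world.prey_pos, world.prey_heading
    groups = _metrics.find_groups(pos, world.cfg.prey_perception)
    _, mean_density = _metrics.local_density(pos, world.cfg.prey_perception)
    return (world.step_count, mean_density, len(groups.groups),
            _metrics.polarization(head), _metrics.rotation(pos, head),
            world.counts["death"], world.counts["capture"])
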