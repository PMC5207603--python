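"""Six-parameter summaries of evolved rule bases.

For each rule base: the attention proportions rho_living_area, rho_predator
and rho_prey (the average per-rule fraction of antecedents referring to the
living area, the nearest predator and the interacting prey individual —
they sum to 1), specificity (mean of (a_i - 1)/(m - 1), 0 when every rule
has a single antecedent, 1 when every rule uses the maximum m), bias (the
mean consequent centroid rescaled to [0, 1]: below 0.5 prefers left turns,
above 0.5 right turns) and size (rule count over the 50-rule upper bound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .fuzzy import (
    MAX_ANTECEDENTS,
    MAX_RULES,
    OUTPUT_VARIABLE,
    VARIABLE_ASPECT,
    FuzzyRuleBase,
)

__all__ = [
    "RuleBaseSummary",
    "attention_proportions",
    "specificity",
    "bias",
    "size_fraction",
    "summarize_rulebase",
    "summarize_pool",
]

_CENTROIDS = {name: f.centroid for name, f in OUTPUT_VARIABLE.values}


@dataclass(frozen=True)
class RuleBaseSummary:
    rho_living_area: float
    rho_predator: float
    rho_prey: float
    specificity: float
    bias: float
    size: float


def attention_proportions(rb: FuzzyRuleBase) -> tuple[float, float, float]:
    """(rho_living_area, rho_predator, rho_prey); sums to 1 for any
    non-empty rule base."""
    if len(rb) == 0:
        raise ValueError("attention proportions undefined for an empty rule base")
    acc = {"living_area": 0.0, "predator": 0.0, "prey": 0.0}
    for rule in rb:
        a = len(rule.antecedents)
        for var, _ in rule.antecedents:
            acc[VARIABLE_ASPECT[var]] += 1.0 / a
    n = len(rb)
    return acc["living_area"] / n, acc["predator"] / n, acc["prey"] / n


def specificity(rb: FuzzyRuleBase, m: int = MAX_ANTECEDENTS) -> float:
    """Mean of (a_i - 1) / (m - 1) over the rules."""
    if len(rb) == 0:
        raise ValueError("specificity undefined for an empty rule base")
    if m <= 1:
        raise ValueError("maximum antecedent count must exceed 1")
    return sum((len(r.antecedents) - 1) / (m - 1) for r in rb) / len(rb)


def bias(rb: FuzzyRuleBase) -> float:
    """Turning-side preference: (1/2n) * sum(1 + o_i / 180), where o_i is the
    geometric centroid of the consequent triangle."""
    if len(rb) == 0:
        raise ValueError("bias undefined for an empty rule base")
    return sum(1.0 + _CENTROIDS[r.consequent] / 180.0 for r in rb) / (2 * len(rb))


def size_fraction(rb: FuzzyRuleBase, upper: int = MAX_RULES) -> float:
    """Rule count divided by the maximum number of rules possible."""
    if len(rb) == 0:
        raise ValueError("size undefined for an empty rule base")
    return len(rb) / upper


def summarize_rulebase(rb: FuzzyRuleBase) -> RuleBaseSummary:
    rl, rp, ri = attention_proportions(rb)
    return RuleBaseSummary(rl, rp, ri, specificity(rb), bias(rb), size_fraction(rb))


def summarize_pool(rulebases: Iterable[FuzzyRuleBase],
                   pool_id: Optional[str] = None,
                   behaviour_class: Optional[str] = None) -> pd.DataFrame:
    """One row of the six parameters per rule base; medians in ``df.attrs``."""
    rows = []
    for rb in rulebases:
        s = summarize_rulebase(rb)
        row = {"rho_living_area": s.rho_living_area, "rho_predator": s.rho_predator,
               "rho_prey": s.rho_prey, "specificity": s.specificity,
               "bias": s.bias, "size": s.size}
        if pool_id is not None:
            row["pool_id"] = pool_id
        if behaviour_class is not None:
            row["behaviour_class"] = behaviour_class
        rows.append(row)
    df = pd.DataFrame.from_records(rows)
    numeric = ["rho_living_area", "rho_predator", "rho_prey",
               "specificity", "bias", "size"]
    df.attrs["medians"] = {c: float(df[c].median()) for c in numeric} if len(df) else {}
    return df
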