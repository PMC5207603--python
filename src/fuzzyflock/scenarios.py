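"""Scripted scenes: deterministic geometric fixtures for the metrics and the
inference engine, independent of any evolutionary run.

``make_parallel``, ``make_mill`` and ``make_swarm`` exercise the polar,
milling and swarm regimes of the polarization/rotation classifier;
``make_fig1_scene`` builds the one-prey/one-predator scene in which the
predator sits at relative bearing -126 degrees and the prey carries the
two-rule base {bearing left -> turn right; bearing behind -> no turn}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fuzzy import FuzzyRule, FuzzyRuleBase, wrap_angle
from .world import relative_bearing

__all__ = [
    "ScriptedScene",
    "make_parallel",
    "make_mill",
    "make_swarm",
    "make_fig1_scene",
    "FIG1_RULEBASE",
]

#: Two-rule reconstruction of the worked inference example; validated by
#: reproducing both its printed values (activation 0.6, output 54.375).
FIG1_RULEBASE = FuzzyRuleBase((
    FuzzyRule((("predator.relative_bearing", "left"),), "right"),
    FuzzyRule((("predator.relative_bearing", "behind"),), "none"),
))


@dataclass
class ScriptedScene:
    positions: np.ndarray
    headings: np.ndarray
    predator_position: Optional[np.ndarray] = None
    predator_heading: Optional[float] = None
    rulebase: Optional[FuzzyRuleBase] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = wrap_angle(np.asarray(self.headings, dtype=float))
        if not (np.isfinite(self.positions).all() and np.isfinite(self.headings).all()):
            raise ValueError("scene coordinates must be finite")


def make_parallel(n: int, spacing: float = 10.0, heading: float = 0.0) -> ScriptedScene:
    """A lattice of agents with identical headings (polar regime)."""
    if n < 2:
        raise ValueError("need at least 2 agents")
    cols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    pos = np.stack([(idx % cols) * spacing, (idx // cols) * spacing], axis=1)
    return ScriptedScene(pos, np.full(n, float(heading)))


def make_mill(n: int, radius: float = 30.0, sense: int = 1) -> ScriptedScene:
    """Agents evenly spaced on a circle with tangential headings (milling
    regime); ``sense`` +1 or -1 picks the direction of rotation."""
    if n < 3:
        raise ValueError("need at least 3 agents")
    if sense not in (1, -1):
        raise ValueError("sense must be +1 or -1")
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pos = radius * np.stack([np.cos(th), np.sin(th)], axis=1)
    headings = wrap_angle(np.degrees(th) + sense * 90.0)
    return ScriptedScene(pos, headings)


def make_swarm(n: int, radius: float = 100.0,
               rng: Optional[np.random.Generator] = None, seed: int = 0) -> ScriptedScene:
    """Uniform positions on a disc with i.i.d. uniform headings (swarm
    regime; expected polarization and rotation shrink as 1/sqrt(n))."""
    if n < 2:
        raise ValueError("need at least 2 agents")
    rng = rng if rng is not None else np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
    headings = wrap_angle(rng.random(n) * 360.0 - 180.0)
    return ScriptedScene(pos, headings)


def make_fig1_scene(distance: float = 50.0) -> ScriptedScene:
    """One prey (at the origin, heading 0) and one predator placed so that
    its relative bearing is exactly -126 degrees, plus the two-rule base."""
    bearing = -126.0
    ang = np.radians(bearing)  # prey heading is 0, so bearing = world angle
    pred = distance * np.array([np.cos(ang), np.sin(ang)])
    scene = ScriptedScene(np.zeros((1, 2)), np.zeros(1),
                          predator_position=pred,
                          predator_heading=float(wrap_angle(bearing + 180.0)),
                          rulebase=FIG1_RULEBASE)
    assert abs(relative_bearing(scene.positions[0], 0.0, pred) - bearing) < 1e-9
    return scene
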