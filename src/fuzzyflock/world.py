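"""The 2D artificial world: prey/predator kinematics, perception, energy
accounting, predator tactics and scheduling, and the synchronous update loop.

Conventions
-----------
Angles are degrees. A heading h corresponds to the unit velocity
(cos h, sin h). Relative bearing is the wrapped signed difference between
the direction to the target and the agent's own heading: 0 is dead ahead,
negative is on the agent's left, +/-180 directly behind (the plane is viewed
so that positive rotation turns to the right). A positive heading change
therefore turns the agent to its right.

Prey move at constant speed; their desired heading change each step comes
from their own evolvable fuzzy rule base. Predators cycle between an
off-world waiting state and hunts of fixed duration, entering at a random
point on the ambush circle heading toward the centre, with one of four
target-selection tactics chosen uniformly at random on each entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .fuzzy import (
    DATA_BASE,
    DefuzzGrid,
    FuzzyRule,
    FuzzyRuleBase,
    InputVector,
    PopulationInference,
    degree_table_from_crisp,
    infer_heading_change,
    wrap_angle,
)

__all__ = [
    "WorldConfig",
    "PreyState",
    "PredatorState",
    "World",
    "step_world",
    "relative_bearing",
    "relative_heading",
    "closest_border_point",
    "sample_interaction_partner",
    "build_perception",
    "select_target",
    "predator_step",
    "PREDATOR_RULEBASE",
    "ST_TACTICS",
    "TACTICS",
]

ST_TACTICS = ("nearest", "most_isolated", "most_central")
TACTICS = ST_TACTICS + ("hda",)

#: Minimal preset pursuit controller: steer by the target's relative bearing
#: through the same inference engine the prey use.
PREDATOR_RULEBASE = FuzzyRuleBase((
    FuzzyRule((("predator.relative_bearing", "left"),), "left"),
    FuzzyRule((("predator.relative_bearing", "in front"),), "none"),
    FuzzyRule((("predator.relative_bearing", "right"),), "right"),
    FuzzyRule((("predator.relative_bearing", "behind"),), "hard right"),
))


@dataclass
class WorldConfig:
    """World, prey and predator parameters (distances in arbitrary units)."""

    # prey
    n_prey: int = 100
    spawn_radius: float = 325.0
    living_area_side: float = 375.0
    prey_size: float = 1.0
    prey_speed: float = 2.0
    prey_perception: float = 100.0
    initial_energy: float = 1000.0
    foraging_gain: float = 1.0
    collision_penalty: float = -10.0
    wandering_penalty: float = -10.0
    # predators
    n_predators: int = 16
    ambush_distance: float = 400.0
    re_enter_low: int = 600
    re_enter_high: int = 1200
    hunt_duration: int = 600
    st_size: float = 6.0
    st_speed: float = 3.0
    st_perception: float = 500.0
    st_catch: float = 6.0
    hda_size: float = 12.0
    hda_speed: float = 1.5
    hda_perception: float = 500.0
    hda_catch: float = 12.0
    # numerics
    defuzz_resolution: float = 0.25
    epsilon: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        for name in ("spawn_radius", "living_area_side", "prey_size", "prey_speed",
                     "prey_perception", "st_speed", "hda_speed", "ambush_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.collision_penalty > 0 or self.wandering_penalty > 0:
            raise ValueError("penalties must be non-positive")
        if self.re_enter_low > self.re_enter_high:
            raise ValueError("re-enter interval low must be <= high")

    def predator_params(self, tactic: str) -> tuple[float, float, float, float]:
        """(size, speed, perception, catch) for a tactic."""
        if tactic == "hda":
            return self.hda_size, self.hda_speed, self.hda_perception, self.hda_catch
        return self.st_size, self.st_speed, self.st_perception, self.st_catch


@dataclass
class PreyState:
    """Read-only snapshot of one prey agent."""

    id: int
    position: np.ndarray
    heading: float
    energy: float
    rulebase: FuzzyRuleBase
    birth_step: int


@dataclass
class PredatorState:
    id: int
    tactic: str
    position: np.ndarray
    heading: float
    on_world: bool = False
    target_id: Optional[int] = None        # prey slot for ST tactics
    target_point: Optional[np.ndarray] = None  # attack point for HDA
    steps_remaining: int = 0               # of the current hunt
    countdown: int = 0                     # re-entry timer while off-world


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def relative_bearing(pos, heading, target) -> float:
    """Bearing of target as seen from (pos, heading), in (-180, 180].

    0 = dead ahead, negative = target on the agent's left.
    """
    pos = np.asarray(pos, dtype=float)
    target = np.asarray(target, dtype=float)
    d = target - pos
    if np.hypot(d[0], d[1]) == 0.0:
        raise ValueError("bearing undefined for coincident points")
    ang = np.degrees(np.arctan2(d[1], d[0]))
    return float(wrap_angle(ang - heading))


def relative_heading(own: float, other: float) -> float:
    """Wrapped signed difference other - own in (-180, 180]."""
    return float(wrap_angle(other - own))


def closest_border_point(pos, side: float):
    """Euclidean nearest point on the perimeter of the axis-aligned square of
    the given side length centred at the origin; valid inside and outside.

    Interior ties are broken toward the +x edge.
    """
    pos = np.asarray(pos, dtype=float)
    half = side / 2.0
    x, y = float(pos[0]), float(pos[1])
    if abs(x) > half or abs(y) > half:  # outside: clamp onto the square
        p = np.array([np.clip(x, -half, half), np.clip(y, -half, half)])
        return p, float(np.hypot(*(pos - p)))
    gaps = (half - x, x + half, half - y, y + half)  # +x, -x, +y, -y edges
    k = int(np.argmin(gaps))
    p = (np.array([half, y]), np.array([-half, y]),
         np.array([x, half]), np.array([x, -half]))[k]
    return p, float(gaps[k])


def _unit(heading_deg):
    h = np.radians(np.asarray(heading_deg, dtype=float))
    return np.stack([np.cos(h), np.sin(h)], axis=-1)


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------

def sample_interaction_partner(
    focal_pos, focal_idx: Optional[int], positions: np.ndarray,
    perception: float, rng: np.random.Generator, eps: float = 1e-6,
) -> Optional[int]:
    """Sample one conspecific to interact with, with probability inversely
    proportional to distance; None when no conspecific is within perception.
    """
    pos = np.asarray(positions, dtype=float)
    d = np.hypot(*(pos - np.asarray(focal_pos, dtype=float)).T)
    if focal_idx is not None:
        d[focal_idx] = np.inf
    mask = d <= perception
    if not np.any(mask):
        return None
    w = np.where(mask, 1.0 / np.maximum(d, eps), 0.0)
    w /= w.sum()
    return int(rng.choice(len(pos), p=w))


def build_perception(world: "World", idx: int,
                     rng: Optional[np.random.Generator] = None) -> InputVector:
    """Perception snapshot of one prey agent (the eight nullable crisp inputs).

    Perception is limited by distance only: no occlusion, no blind angle.
    """
    cfg = world.cfg
    rng = rng if rng is not None else world.rng
    pos = world.prey_pos[idx]
    heading = float(world.prey_heading[idx])
    kw: dict = {}

    partner = sample_interaction_partner(
        pos, idx, world.prey_pos, cfg.prey_perception, rng, cfg.epsilon)
    if partner is not None:
        ppos = world.prey_pos[partner]
        kw["interaction_distance"] = float(np.hypot(*(ppos - pos)))
        kw["interaction_bearing"] = relative_bearing(pos, heading, ppos)
        kw["interaction_heading"] = relative_heading(heading, float(world.prey_heading[partner]))

    on_world = [p for p in world.predators if p.on_world]
    if on_world:
        dists = [float(np.hypot(*(p.position - pos))) for p in on_world]
        j = int(np.argmin(dists))
        if dists[j] <= cfg.prey_perception:
            p = on_world[j]
            kw["predator_distance"] = dists[j]
            kw["predator_bearing"] = relative_bearing(pos, heading, p.position)
            kw["predator_heading"] = relative_heading(heading, p.heading)

    bp, bd = closest_border_point(pos, cfg.living_area_side)
    if bd <= cfg.prey_perception:
        kw["area_distance"] = bd
        kw["area_bearing"] = relative_bearing(pos, heading, bp)
    return InputVector(**kw)


# ---------------------------------------------------------------------------
# Predators
# ---------------------------------------------------------------------------

def select_target(pred: PredatorState, prey_pos: np.ndarray, cfg: WorldConfig,
                  pair_dist: Optional[np.ndarray] = None):
    """Choose a target under the predator's tactic.

    ST tactics return a prey slot index (persistent until capture or target
    death); the HDA tactic returns the attack point, recomputed every step.
    Returns None when no prey is within the predator's perception distance.
    """
    size, speed, perception, catch = cfg.predator_params(pred.tactic)
    d = np.hypot(*(prey_pos - pred.position).T)
    perceived = np.flatnonzero(d <= perception)
    if perceived.size == 0:
        return None
    if pair_dist is None:
        diff = prey_pos[:, None, :] - prey_pos[None, :, :]
        pair_dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(pair_dist, np.inf)
    if pred.tactic == "nearest":
        return int(perceived[np.argmin(d[perceived])])
    if pred.tactic == "most_isolated":
        nn = pair_dist[perceived].min(axis=1)
        return int(perceived[np.argmax(nn)])
    if pred.tactic == "most_central":
        centroid = prey_pos[perceived].mean(axis=0)
        dc = np.hypot(*(prey_pos[perceived] - centroid).T)
        return int(perceived[np.argmin(dc)])
    if pred.tactic == "hda":
        counts = (pair_dist[perceived] <= catch).sum(axis=1)
        return prey_pos[perceived[int(np.argmax(counts))]].copy()
    raise ValueError(f"unknown tactic {pred.tactic!r}")


def predator_step(pred: PredatorState, target_pos, target_heading: float,
                  grid: Optional[DefuzzGrid] = None) -> float:
    """Heading change (degrees) of a hunting predator toward a target pose,
    produced by the preset four-rule pursuit controller."""
    d = float(np.hypot(*(np.asarray(target_pos, float) - pred.position)))
    if d == 0.0:
        return 0.0
    iv = InputVector(
        predator_distance=d,
        predator_bearing=relative_bearing(pred.position, pred.heading, target_pos),
        predator_heading=relative_heading(pred.heading, target_heading),
    )
    return infer_heading_change(PREDATOR_RULEBASE, iv, grid)


_PURSUIT_LUT: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _pursuit_table(grid: DefuzzGrid) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated pursuit controller: turn angle as a function of the target's
    relative bearing. The controller depends on the bearing alone, so its
    response is precomputed on a dense bearing grid and interpolated
    (piecewise-linear; error far below a hundredth of a degree)."""
    key = grid.resolution
    if key not in _PURSUIT_LUT:
        bearings = np.linspace(-180.0, 180.0, 2881)
        lv = DATA_BASE["predator.relative_bearing"]
        acts = lv.memberships(bearings)  # (B, 4): left, in front, right, behind
        cons = [grid.value_index[r.consequent] for r in PREDATOR_RULEBASE]
        one_minus = np.ones((bearings.size, grid.x.size))
        for j, ci in enumerate(cons):
            one_minus *= 1.0 - acts[:, j:j + 1] * grid.value_curves[ci]
        turns = grid.centroid_rows(1.0 - one_minus)
        _PURSUIT_LUT[key] = (bearings, turns)
    return _PURSUIT_LUT[key]


def pursuit_turn(pred: PredatorState, target_pos, grid: DefuzzGrid) -> float:
    """Fast path of :func:`predator_step` via the tabulated controller."""
    dx = float(target_pos[0]) - float(pred.position[0])
    dy = float(target_pos[1]) - float(pred.position[1])
    if dx == 0.0 and dy == 0.0:
        return 0.0
    b = -((-(math.degrees(math.atan2(dy, dx)) - pred.heading) + 180.0) % 360.0 - 180.0)
    bearings, turns = _pursuit_table(grid)
    f = (b + 180.0) / 360.0 * (bearings.size - 1)
    i = min(int(f), bearings.size - 2)
    t = f - i
    return float((1.0 - t) * turns[i] + t * turns[i + 1])


# ---------------------------------------------------------------------------
# The world
# ---------------------------------------------------------------------------

#: evolution_hook(world, dead_slot, survivors) -> FuzzyRuleBase for the newborn
EvolutionHook = Callable[["World", int, np.ndarray], FuzzyRuleBase]


class World:
    """Synchronous discrete-time simulation state.

    The prey population size is constant: each dead or captured prey is
    replaced in the same step by a newborn whose rule base comes from the
    evolution hook (genetic during evolution, pool sampling during
    validation, a clone by default).

    All randomness flows through one seeded generator in a fixed order per
    step: interaction-partner draws, then replacement draws per dead slot in
    ascending slot order, then predator re-entry draws in predator order.
    """

    def __init__(self, cfg: WorldConfig, rulebases: Sequence[FuzzyRuleBase],
                 rng: Optional[np.random.Generator] = None,
                 grid: Optional[DefuzzGrid] = None, log_events: bool = False):
        if len(rulebases) != cfg.n_prey:
            raise ValueError("need one rule base per prey agent")
        self.cfg = cfg
        self.rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        self.grid = grid if grid is not None else DefuzzGrid(cfg.defuzz_resolution)
        self.engine = PopulationInference(list(rulebases), self.grid)
        self.step_count = 0
        n = cfg.n_prey
        self.prey_pos = np.zeros((n, 2))
        self.prey_heading = np.zeros(n)
        self.prey_energy = np.full(n, cfg.initial_energy)
        self.prey_birth = np.zeros(n, dtype=np.int64)
        self.prey_uid = np.arange(n, dtype=np.int64)
        self._next_uid = n
        # per-lifetime penalty counters (energy bookkeeping audit)
        self.prey_collisions = np.zeros(n, dtype=np.int64)
        self.prey_wanders = np.zeros(n, dtype=np.int64)
        self.predators: list[PredatorState] = []
        for i in range(cfg.n_predators):
            tactic = TACTICS[int(self.rng.integers(len(TACTICS)))]
            countdown = int(self.rng.integers(cfg.re_enter_low, cfg.re_enter_high + 1))
            self.predators.append(PredatorState(
                id=i, tactic=tactic, position=np.zeros(2), heading=0.0,
                on_world=False, countdown=countdown))
        self.log_events = log_events
        self.events: list[tuple] = []
        self.counts = {"capture": 0, "collision": 0, "wander": 0,
                       "death": 0, "birth": 0}

    # -- initial placement --------------------------------------------------

    def scatter_prey(self) -> None:
        """Uniform random positions on the spawn disc, uniform headings."""
        n = self.cfg.n_prey
        r = self.cfg.spawn_radius * np.sqrt(self.rng.random(n))
        th = self.rng.random(n) * 2 * np.pi
        self.prey_pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        self.prey_heading = wrap_angle(self.rng.random(n) * 360.0 - 180.0)

    @property
    def rulebases(self) -> list[FuzzyRuleBase]:
        return self.engine.rulebases

    def prey_state(self, idx: int) -> PreyState:
        return PreyState(idx, self.prey_pos[idx].copy(), float(self.prey_heading[idx]),
                         float(self.prey_energy[idx]), self.rulebases[idx],
                         int(self.prey_birth[idx]))

    def _log(self, event: str, *ids) -> None:
        self.counts[event] += 1
        if self.log_events:
            self.events.append((self.step_count, event) + ids)

    # -- perception / decision (batched) ------------------------------------

    def _pair_distances(self) -> np.ndarray:
        d = squareform(pdist(self.prey_pos))
        np.fill_diagonal(d, np.inf)
        return d

    _pair_cache: Optional[np.ndarray] = None

    def _degree_table(self, pair_dist: np.ndarray) -> np.ndarray:
        """Crisp perceptions of every prey, fuzzified into the degree table.

        Crisp column order follows INPUT_VARIABLE_NAMES: interaction
        distance/bearing/heading, predator distance/bearing/heading,
        living-area distance/bearing. Null variable groups (nothing within
        perception) zero their block so no rule mentioning them fires.
        """
        cfg = self.cfg
        n = cfg.n_prey
        pos, heading = self.prey_pos, self.prey_heading
        X = np.zeros((n, 8))
        null = np.ones((n, 8), dtype=bool)

        # interaction partner: one weighted draw per prey, every step
        mask = pair_dist <= cfg.prey_perception
        w = np.where(mask, 1.0 / np.maximum(pair_dist, cfg.epsilon), 0.0)
        total = w.sum(axis=1)
        u = self.rng.random(n) * total
        partner = np.minimum((np.cumsum(w, axis=1) <= u[:, None]).sum(axis=1), n - 1)
        has_partner = total > 0.0
        rel = pos[partner] - pos
        X[:, 0] = pair_dist[np.arange(n), partner]
        X[:, 1] = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) - heading
        X[:, 2] = heading[partner] - heading
        null[:, 0:3] = ~has_partner[:, None]

        # nearest on-world predator, gated by prey perception distance
        on_world = [p for p in self.predators if p.on_world]
        if on_world:
            ppos = np.stack([p.position for p in on_world])
            phead = np.array([p.heading for p in on_world])
            dp = np.hypot(*(pos[:, None, :] - ppos[None, :, :]).transpose(2, 0, 1))
            j = np.argmin(dp, axis=1)
            dmin = dp[np.arange(n), j]
            relp = ppos[j] - pos
            X[:, 3] = dmin
            X[:, 4] = np.degrees(np.arctan2(relp[:, 1], relp[:, 0])) - heading
            X[:, 5] = phead[j] - heading
            null[:, 3:6] = (dmin > cfg.prey_perception)[:, None]

        # living-area border
        half = cfg.living_area_side / 2.0
        x, y = pos[:, 0], pos[:, 1]
        outside = (np.abs(x) > half) | (np.abs(y) > half)
        cx = np.clip(x, -half, half)
        cy = np.clip(y, -half, half)
        gaps = np.stack([half - x, x + half, half - y, y + half], axis=1)
        k = np.argmin(gaps, axis=1)
        bx = x.copy()
        by = y.copy()
        bx[k == 0] = half
        bx[k == 1] = -half
        by[k == 2] = half
        by[k == 3] = -half
        bx[outside] = cx[outside]
        by[outside] = cy[outside]
        bdist = np.where(outside, np.hypot(x - cx, y - cy),
                         gaps[np.arange(n), k])
        X[:, 6] = bdist
        X[:, 7] = np.degrees(np.arctan2(by - y, np.where(
            (bx == x) & (by == y), 1.0, bx - x))) - heading
        null[:, 6:8] = (bdist > cfg.prey_perception)[:, None]
        return degree_table_from_crisp(X, null)

    # -- one synchronous update ---------------------------------------------

    def step(self, evolution_hook: Optional[EvolutionHook] = None) -> None:
        cfg = self.cfg
        n = cfg.n_prey
        # pre-step distances equal last step's post-move distances unless a
        # respawn has moved an agent in between
        pair_dist = self._pair_cache if self._pair_cache is not None \
            else self._pair_distances()
        self._pair_cache = None

        # (1) all decisions from the pre-step state
        D = self._degree_table(pair_dist)
        prey_turn = self.engine.infer(D)

        pred_turn: dict[int, float] = {}
        for p in self.predators:
            if not p.on_world:
                continue
            if p.tactic == "hda":
                point = select_target(p, self.prey_pos, cfg, pair_dist)
                p.target_point = point
                if point is not None:
                    pred_turn[p.id] = pursuit_turn(p, point, self.grid)
            else:
                if p.target_id is None:
                    tgt = select_target(p, self.prey_pos, cfg, pair_dist)
                    p.target_id = tgt
                if p.target_id is not None:
                    pred_turn[p.id] = pursuit_turn(
                        p, self.prey_pos[p.target_id], self.grid)

        # (2) move: full defuzzified turn, then constant-speed advance
        self.prey_heading = wrap_angle(self.prey_heading + prey_turn)
        self.prey_pos = self.prey_pos + cfg.prey_speed * _unit(self.prey_heading)
        for p in self.predators:
            if p.on_world:
                h = p.heading + pred_turn.get(p.id, 0.0)
                p.heading = -((-h + 180.0) % 360.0 - 180.0)
                speed = cfg.predator_params(p.tactic)[1]
                rad = math.radians(p.heading)
                p.position = p.position + np.array(
                    [speed * math.cos(rad), speed * math.sin(rad)])

        # (3) energy: foraging gain, collision and wandering penalties
        self.prey_energy += cfg.foraging_gain
        post = self._pair_distances()
        colliding = (post < 2.0 * cfg.prey_size).any(axis=1)
        self.prey_energy[colliding] += cfg.collision_penalty
        self.prey_collisions += colliding
        half = cfg.living_area_side / 2.0
        wandering = (np.abs(self.prey_pos) > half).any(axis=1)
        self.prey_energy[wandering] += cfg.wandering_penalty
        self.prey_wanders += wandering
        for i in np.flatnonzero(colliding):
            self._log("collision", int(self.prey_uid[i]))
        for i in np.flatnonzero(wandering):
            self._log("wander", int(self.prey_uid[i]))

        # (4) captures
        captured = np.zeros(n, dtype=bool)
        for p in self.predators:
            if not p.on_world:
                continue
            catch = cfg.predator_params(p.tactic)[3]
            if p.tactic == "hda":
                hit = np.hypot(*(self.prey_pos - p.position).T) <= catch
                for i in np.flatnonzero(hit & ~captured):
                    self._log("capture", p.id, int(self.prey_uid[i]))
                captured |= hit
            else:
                t = p.target_id
                if t is not None and not captured[t] and \
                        float(np.hypot(*(self.prey_pos[t] - p.position))) <= catch:
                    captured[t] = True
                    self._log("capture", p.id, int(self.prey_uid[t]))
                    p.target_id = None

        # (5) deaths and replacement (population size conserved)
        dead = captured | (self.prey_energy <= 0.0)
        if not dead.any():
            self._pair_cache = post
        survivors = np.flatnonzero(~dead)
        for p in self.predators:  # a vanished ST target forces reselection
            if p.target_id is not None and dead[p.target_id]:
                p.target_id = None
        for i in np.flatnonzero(dead):
            self._log("death", int(self.prey_uid[i]))
            if evolution_hook is not None:
                rb = evolution_hook(self, int(i), survivors)
            else:
                rb = self.rulebases[int(i)]
            self._spawn(int(i), rb)

        # (6) predator schedule
        for p in self.predators:
            if p.on_world:
                p.steps_remaining -= 1
                if p.steps_remaining <= 0:
                    p.on_world = False
                    p.target_id = None
                    p.target_point = None
                    p.countdown = int(self.rng.integers(
                        cfg.re_enter_low, cfg.re_enter_high + 1))
            else:
                p.countdown -= 1
                if p.countdown <= 0:
                    self._enter_predator(p)

        self.step_count += 1

    def _spawn(self, slot: int, rb: FuzzyRuleBase) -> None:
        cfg = self.cfg
        r = cfg.spawn_radius * np.sqrt(self.rng.random())
        th = self.rng.random() * 2 * np.pi
        self.prey_pos[slot] = (r * np.cos(th), r * np.sin(th))
        self.prey_heading[slot] = float(wrap_angle(self.rng.random() * 360.0 - 180.0))
        self.prey_energy[slot] = cfg.initial_energy
        self.prey_birth[slot] = self.step_count + 1
        self.prey_collisions[slot] = 0
        self.prey_wanders[slot] = 0
        self.prey_uid[slot] = self._next_uid
        self._next_uid += 1
        self.engine.replace(slot, rb)
        self._log("birth", int(self.prey_uid[slot]))

    def _enter_predator(self, p: PredatorState) -> None:
        cfg = self.cfg
        p.tactic = TACTICS[int(self.rng.integers(len(TACTICS)))]
        th = self.rng.random() * 2 * np.pi
        p.position = cfg.ambush_distance * np.array([np.cos(th), np.sin(th)])
        p.heading = float(wrap_angle(np.degrees(th) + 180.0))
        p.on_world = True
        p.steps_remaining = cfg.hunt_duration
        p.target_id = None
        p.target_point = None


def step_world(world: World, evolution_hook: Optional[EvolutionHook] = None) -> World:
    """Advance the world one synchronous update step (in place)."""
    world.step(evolution_hook)
    return world
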