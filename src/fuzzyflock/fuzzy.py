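"""Linguistic fuzzy rule-based inference for prey and predator agents.

A Mamdani-style controller: linguistic variables are decomposed into
linguistic values defined as triangular fuzzy numbers (or periodic
triangular fuzzy numbers for angular "behind"/"opposite" values), crisp
inputs are treated as singleton fuzzy values, conjunction and implication
use the product t-norm, rules are aggregated with the probabilistic sum
s-norm (x + y - xy), and the crisp output (desired change in heading, in
degrees) is obtained by centre-of-gravity defuzzification over a sampled
curve on [-180, 180].

The fuzzy *data base* (membership function definitions) is fixed; only the
*rule base* of each agent varies (and evolves, see :mod:`fuzzyflock.evolution`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

try:  # optional JIT fast path for whole-population inference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco

__all__ = [
    "TriangularFuzzyNumber",
    "PeriodicTriangularFuzzyNumber",
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyRuleBase",
    "InputVector",
    "DefuzzGrid",
    "DATA_BASE",
    "OUTPUT_VARIABLE",
    "INPUT_VARIABLE_NAMES",
    "tri_membership",
    "periodic_membership",
    "rule_activation",
    "aggregate_consequents",
    "centroid_defuzzify",
    "infer_heading_change",
    "mirror_rule",
    "mirror_rulebase",
    "rulebase_to_dict",
    "rulebase_from_dict",
    "rulebase_to_json",
    "rulebase_from_json",
    "rule_to_sentence",
    "rulebase_pretty",
    "wrap_angle",
    "PopulationInference",
]


def wrap_angle(x):
    """Wrap an angle (degrees) into the half-open interval (-180, 180]."""
    return -((-np.asarray(x) + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# Membership primitives
# ---------------------------------------------------------------------------

def _tri_eval(x, l, m, r):
    """Piecewise-linear triangle evaluated element-wise.

    A zero-width side (l == m or m == r) is treated as a crisp shoulder:
    membership is 1 on that side's boundary (the edge values of the data
    base, e.g. <0,0,10> and <60,100,100>, are flat at their peak).
    """
    x, l, m, r = np.broadcast_arrays(np.asarray(x, dtype=float), l, m, r)
    dl = m - l
    dr = r - m
    # a degenerate side imposes no constraint (ones); the outside mask zeroes
    left = np.ones(x.shape)
    np.divide(x - l, dl, out=left, where=dl > 0)
    right = np.ones(x.shape)
    np.divide(r - x, dr, out=right, where=dr > 0)
    mu = np.clip(np.minimum(left, right), 0.0, 1.0)
    return np.where((x < l) | (x > r), 0.0, mu)


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Triangular fuzzy number <l, m, r> with membership 0 outside [l, r]."""

    l: float
    m: float
    r: float

    def __post_init__(self):
        if not (self.l <= self.m <= self.r):
            raise ValueError(f"requires l <= m <= r, got {self}")

    def membership(self, x):
        return _tri_eval(x, self.l, self.m, self.r)

    @property
    def centroid(self) -> float:
        """Geometric centroid of the triangle, (l + m + r) / 3."""
        return (self.l + self.m + self.r) / 3.0


@dataclass(frozen=True)
class PeriodicTriangularFuzzyNumber:
    """Periodic triangular fuzzy number <l, m, r>_c.

    The triangle is evaluated on the wrapped coordinate y = (x - l) mod c,
    so membership is invariant under x -> x + c and always lies in [0, 1].
    """

    l: float
    m: float
    r: float
    c: float = 360.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("period c must be positive")

    def membership(self, x):
        y = (np.asarray(x, dtype=float) - self.l) % self.c
        return _tri_eval(y, 0.0, (self.m - self.l) % self.c, (self.r - self.l) % self.c)

    @property
    def centroid(self) -> float:
        # centroid of the unwrapped triangle, mapped back near its peak
        m = self.l + (self.m - self.l) % self.c
        r = self.l + (self.r - self.l) % self.c
        return (self.l + m + r) / 3.0


FuzzySet = TriangularFuzzyNumber | PeriodicTriangularFuzzyNumber


def tri_membership(x, f: TriangularFuzzyNumber):
    """Degree of membership of crisp x in a triangular fuzzy number."""
    out = f.membership(x)
    return float(out) if np.isscalar(x) else out


def periodic_membership(x, f: PeriodicTriangularFuzzyNumber):
    """Degree of membership of crisp x in a periodic triangular fuzzy number."""
    out = f.membership(x)
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# Data base (fixed membership-function definitions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinguisticVariable:
    """A named input or output variable decomposed into linguistic values.

    ``clamp`` bounds crisp inputs before membership evaluation (distances
    saturate at the perception limit, where the outer "far" value is flat
    at its peak); angular variables are wrapped into (-180, 180] instead.
    """

    name: str
    values: tuple[tuple[str, FuzzySet], ...]
    clamp: Optional[tuple[float, float]] = None
    angular: bool = False

    def __post_init__(self):
        names = [n for n, _ in self.values]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate value names in {self.name}")

    @property
    def value_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.values)

    def fuzzy_set(self, value_name: str) -> FuzzySet:
        for n, f in self.values:
            if n == value_name:
                return f
        raise KeyError(f"{self.name} has no value {value_name!r}")

    def prepare(self, x):
        """Clamp or wrap a crisp input into the variable's universe."""
        if self.clamp is not None:
            return np.clip(x, *self.clamp)
        if self.angular:
            return wrap_angle(x)
        return x

    @cached_property
    def _params(self):
        """Per-value triangle parameters; periodic values are rewritten as
        plain triangles on the wrapped coordinate (x - l) mod c."""
        L, M, R, shift, period = [], [], [], [], []
        for _, f in self.values:
            if isinstance(f, PeriodicTriangularFuzzyNumber):
                L.append(0.0)
                M.append((f.m - f.l) % f.c)
                R.append((f.r - f.l) % f.c)
                shift.append(f.l)
                period.append(f.c)
            else:
                L.append(f.l)
                M.append(f.m)
                R.append(f.r)
                shift.append(0.0)
                period.append(np.inf)
        return tuple(np.asarray(a, dtype=float) for a in (L, M, R, shift, period))

    def memberships(self, x) -> np.ndarray:
        """Membership of crisp input(s) in every value; shape (..., n_values)."""
        x = self.prepare(np.asarray(x, dtype=float))
        L, M, R, shift, period = self._params
        X = np.where(np.isfinite(period),
                     (x[..., None] - shift) % np.where(np.isfinite(period), period, 1.0),
                     x[..., None])
        return _tri_eval(X, L, M, R)


def _distance_values():
    return (
        ("next", TriangularFuzzyNumber(0, 0, 10)),
        ("close", TriangularFuzzyNumber(0, 15, 40)),
        ("near", TriangularFuzzyNumber(20, 40, 60)),
        ("away", TriangularFuzzyNumber(50, 60, 100)),
        ("far", TriangularFuzzyNumber(60, 100, 100)),
    )


def _bearing_values():
    return (
        ("left", TriangularFuzzyNumber(-180, -90, 0)),
        ("in front", TriangularFuzzyNumber(-90, 0, 90)),
        ("right", TriangularFuzzyNumber(0, 90, 180)),
        ("behind", PeriodicTriangularFuzzyNumber(90, 180, -90, 360)),
    )


def _heading_values():
    return (
        ("left", TriangularFuzzyNumber(-180, -90, 0)),
        ("same", TriangularFuzzyNumber(-90, 0, 90)),
        ("right", TriangularFuzzyNumber(0, 90, 180)),
        ("opposite", PeriodicTriangularFuzzyNumber(90, 180, -90, 360)),
    )


_DIST_CLAMP = (0.0, 100.0)

#: The eight input variables of the prey agent's fuzzy data base. The
#: nearest-predator variables share the interaction membership shapes.
DATA_BASE: dict[str, LinguisticVariable] = {
    v.name: v
    for v in (
        LinguisticVariable("interaction.distance", _distance_values(), clamp=_DIST_CLAMP),
        LinguisticVariable("interaction.relative_bearing", _bearing_values(), angular=True),
        LinguisticVariable("interaction.relative_heading", _heading_values(), angular=True),
        LinguisticVariable("predator.distance", _distance_values(), clamp=_DIST_CLAMP),
        LinguisticVariable("predator.relative_bearing", _bearing_values(), angular=True),
        LinguisticVariable("predator.relative_heading", _heading_values(), angular=True),
        LinguisticVariable("living_area.distance", _distance_values(), clamp=_DIST_CLAMP),
        LinguisticVariable("living_area.relative_bearing", _bearing_values(), angular=True),
    )
}

#: The single output variable: desired change in heading, in degrees.
OUTPUT_VARIABLE = LinguisticVariable(
    "action.heading_change",
    (
        ("hard left", TriangularFuzzyNumber(-180, -180, -90)),
        ("left", TriangularFuzzyNumber(-180, -90, 0)),
        ("none", TriangularFuzzyNumber(-90, 0, 90)),
        ("right", TriangularFuzzyNumber(0, 90, 180)),
        ("hard right", TriangularFuzzyNumber(90, 180, 180)),
    ),
    angular=True,
)

INPUT_VARIABLE_NAMES: tuple[str, ...] = tuple(DATA_BASE)

#: Which aspect of the world each input variable attends to (rule-base stats).
VARIABLE_ASPECT: dict[str, str] = {
    name: ("living_area" if name.startswith("living_area") else
           "predator" if name.startswith("predator") else "prey")
    for name in INPUT_VARIABLE_NAMES
}

MAX_ANTECEDENTS = 4
MAX_RULES = 50

# flat column layout of the population degree table, one block per variable
_VAR_OFFSETS: dict[str, int] = {}
_off = 0
for _name in INPUT_VARIABLE_NAMES:
    _VAR_OFFSETS[_name] = _off
    _off += len(DATA_BASE[_name].values)
TABLE_WIDTH = _off

# packed per-slot triangle parameters for the JIT degree-table kernel
# (periodic values are stored as triangles on the wrapped coordinate)


def _pack_slots():
    L, M, R, shift, period = [], [], [], [], []
    starts, nvals, angular, clamp_hi = [], [], [], []
    for name in INPUT_VARIABLE_NAMES:
        lv = DATA_BASE[name]
        starts.append(len(L))
        nvals.append(len(lv.values))
        angular.append(lv.angular)
        clamp_hi.append(lv.clamp[1] if lv.clamp else np.nan)
        pl, pm, pr, psh, pc = lv._params
        L.extend(pl)
        M.extend(pm)
        R.extend(pr)
        shift.extend(psh)
        period.extend(pc)
    return (np.array(L), np.array(M), np.array(R), np.array(shift),
            np.array(period), np.array(starts, dtype=np.int64),
            np.array(nvals, dtype=np.int64), np.array(angular, dtype=np.uint8),
            np.array(clamp_hi))


(_SLOT_L, _SLOT_M, _SLOT_R, _SLOT_SHIFT, _SLOT_PERIOD,
 _VAR_START, _VAR_NVALS, _VAR_ANGULAR, _VAR_CLAMP_HI) = _pack_slots()


# ---------------------------------------------------------------------------
# Rules and rule bases
# ---------------------------------------------------------------------------

class ConfigurationError(ValueError):
    """A rule refers to an unknown variable or value name."""


@dataclass(frozen=True)
class FuzzyRule:
    """One IF-THEN rule: 1-4 antecedents over distinct input variables and a
    single heading-change consequent."""

    antecedents: tuple[tuple[str, str], ...]
    consequent: str

    def __post_init__(self):
        if not (1 <= len(self.antecedents) <= MAX_ANTECEDENTS):
            raise ConfigurationError(
                f"rule must have 1-{MAX_ANTECEDENTS} antecedents, got {len(self.antecedents)}")
        seen = set()
        for var, val in self.antecedents:
            if var not in DATA_BASE:
                raise ConfigurationError(f"unknown input variable {var!r}")
            if val not in DATA_BASE[var].value_names:
                raise ConfigurationError(f"variable {var!r} has no value {val!r}")
            if var in seen:
                raise ConfigurationError(f"variable {var!r} repeated in antecedents")
            seen.add(var)
        if self.consequent not in OUTPUT_VARIABLE.value_names:
            raise ConfigurationError(f"unknown heading-change value {self.consequent!r}")


@dataclass(frozen=True)
class FuzzyRuleBase:
    """An agent's evolvable chromosome: an ordered multiset of rules.

    Duplicate rules are permitted (crossover works on the joint multiset of
    the parents' rules). Evolution keeps the length within [1, 50]; an empty
    rule base is allowed as a null controller that never turns.
    """

    rules: tuple[FuzzyRule, ...]

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if len(self.rules) > MAX_RULES:
            raise ConfigurationError(f"rule base exceeds {MAX_RULES} rules")

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass(frozen=True)
class InputVector:
    """The eight nullable crisp inputs a prey agent perceives in one step.

    The three interaction inputs are jointly null or jointly present, as are
    the three predator inputs and the two living-area inputs (a null group
    means the corresponding entity is beyond perception distance, so no rule
    mentioning it fires).
    """

    interaction_distance: Optional[float] = None
    interaction_bearing: Optional[float] = None
    interaction_heading: Optional[float] = None
    predator_distance: Optional[float] = None
    predator_bearing: Optional[float] = None
    predator_heading: Optional[float] = None
    area_distance: Optional[float] = None
    area_bearing: Optional[float] = None

    _FIELD_BY_VAR = {
        "interaction.distance": "interaction_distance",
        "interaction.relative_bearing": "interaction_bearing",
        "interaction.relative_heading": "interaction_heading",
        "predator.distance": "predator_distance",
        "predator.relative_bearing": "predator_bearing",
        "predator.relative_heading": "predator_heading",
        "living_area.distance": "area_distance",
        "living_area.relative_bearing": "area_bearing",
    }

    def __post_init__(self):
        groups = (
            ("interaction", (self.interaction_distance, self.interaction_bearing,
                             self.interaction_heading)),
            ("predator", (self.predator_distance, self.predator_bearing,
                          self.predator_heading)),
            ("living area", (self.area_distance, self.area_bearing)),
        )
        for label, vals in groups:
            nulls = [v is None for v in vals]
            if any(nulls) and not all(nulls):
                raise ValueError(f"{label} inputs must be jointly null or present")
        for d in (self.interaction_distance, self.predator_distance, self.area_distance):
            if d is not None and d < 0:
                raise ValueError("distances must be non-negative")

    def get(self, variable: str) -> Optional[float]:
        return getattr(self, self._FIELD_BY_VAR[variable])


# ---------------------------------------------------------------------------
# Inference pipeline
# ---------------------------------------------------------------------------

class DefuzzGrid:
    """Uniform sampling of the output universe [-180, 180].

    Default resolution 0.25 degrees (1441 points) with trapezoidal
    quadrature; precomputes the membership curve of every output value.
    """

    def __init__(self, resolution: float = 0.25):
        n = round(360.0 / resolution) if resolution > 0 else 0
        if n < 2 or abs(n * resolution - 360.0) > 1e-9:
            raise ValueError("resolution must divide 360")
        self.resolution = float(resolution)
        self.x = np.linspace(-180.0, 180.0, n + 1)
        w = np.full_like(self.x, resolution)
        w[0] = w[-1] = resolution / 2.0  # trapezoid end weights
        self._w = w
        self._xw = self.x * w
        #: (n_output_values, n_points) membership curves of the output values
        self.value_curves = np.stack(
            [f.membership(self.x) for _, f in OUTPUT_VARIABLE.values])
        self.value_index = {n: i for i, n in enumerate(OUTPUT_VARIABLE.value_names)}
        # contiguous support [lo, hi] of each output curve (for the JIT path)
        self._support_lo = np.array(
            [int(np.flatnonzero(c > 0)[0]) for c in self.value_curves], dtype=np.int64)
        self._support_hi = np.array(
            [int(np.flatnonzero(c > 0)[-1]) for c in self.value_curves], dtype=np.int64)

    def centroid(self, curve: np.ndarray) -> float:
        den = float(curve @ self._w)
        if den <= 0.0:
            return 0.0
        return float(curve @ self._xw) / den

    def centroid_rows(self, curves: np.ndarray) -> np.ndarray:
        """Row-wise centre of gravity; identically-zero rows map to 0."""
        den = curves @ self._w
        num = curves @ self._xw
        return np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)


_DEFAULT_GRID = DefuzzGrid()


def default_grid() -> DefuzzGrid:
    return _DEFAULT_GRID


def rule_activation(rule: FuzzyRule, inputs: InputVector) -> float:
    """Degree to which a rule fires: product t-norm over its antecedents.

    Exactly 0 when any antecedent variable is null in the inputs.
    """
    degree = 1.0
    for var, val in rule.antecedents:
        x = inputs.get(var)
        if x is None:
            return 0.0
        lv = DATA_BASE[var]
        degree *= float(lv.fuzzy_set(val).membership(lv.prepare(x)))
        if degree == 0.0:
            return 0.0
    return degree


def aggregate_consequents(
    pairs: Iterable[tuple[float, str]], grid: Optional[DefuzzGrid] = None
) -> np.ndarray:
    """Aggregate activated consequents into one curve over [-180, 180].

    Each consequent's membership curve is scaled by its activation (product
    implication) and the scaled curves are combined pointwise with the
    probabilistic sum s-norm; an empty input yields the zero curve.
    """
    grid = grid or _DEFAULT_GRID
    one_minus = np.ones_like(grid.x)
    for activation, value_name in pairs:
        if not 0.0 <= activation <= 1.0:
            raise ValueError("activation outside [0, 1]")
        if activation == 0.0:
            continue
        scaled = activation * grid.value_curves[grid.value_index[value_name]]
        one_minus *= 1.0 - scaled
    return 1.0 - one_minus


def centroid_defuzzify(curve: np.ndarray, grid: Optional[DefuzzGrid] = None) -> float:
    """Centre-of-gravity of a sampled curve; 0 for the identically-zero curve."""
    grid = grid or _DEFAULT_GRID
    if np.any(curve < 0):
        raise ValueError("curve must be non-negative")
    return grid.centroid(np.asarray(curve, dtype=float))


def infer_heading_change(
    rb: FuzzyRuleBase, inputs: InputVector, grid: Optional[DefuzzGrid] = None
) -> float:
    """Full Mamdani pipeline: activate, aggregate, defuzzify.

    Returns the desired heading change in degrees within [-180, 180];
    0 when no rule fires.
    """
    grid = grid or _DEFAULT_GRID
    pairs = [(rule_activation(r, inputs), r.consequent) for r in rb]
    return grid.centroid(aggregate_consequents(pairs, grid))


# ---------------------------------------------------------------------------
# Batched inference over a whole population
# ---------------------------------------------------------------------------

def _compile_rulebase(rb: FuzzyRuleBase):
    """Flatten a rule base into integer arrays for vectorised activation."""
    cols, counts, cons = [], [], []
    for rule in rb:
        for var, val in rule.antecedents:
            cols.append(_VAR_OFFSETS[var] + DATA_BASE[var].value_names.index(val))
        counts.append(len(rule.antecedents))
        cons.append(OUTPUT_VARIABLE.value_names.index(rule.consequent))
    return (np.asarray(cols, dtype=np.int64),
            np.asarray(counts, dtype=np.int64),
            np.asarray(cons, dtype=np.int64))


_COMPILE_CACHE: dict[int, tuple] = {}


def compiled(rb: FuzzyRuleBase):
    key = id(rb)
    hit = _COMPILE_CACHE.get(key)
    if hit is None or hit[0] is not rb:
        hit = (rb, _compile_rulebase(rb))
        if len(_COMPILE_CACHE) > 4096:
            _COMPILE_CACHE.clear()
        _COMPILE_CACHE[key] = hit
    return hit[1]


@_njit(cache=True)
def _degree_kernel(X, null, L, M, R, shift, period, var_start, var_nvals,
                   var_angular, clamp_hi, D):  # pragma: no cover - JIT
    n, n_vars = X.shape
    for i in range(n):
        for v in range(n_vars):
            if null[i, v]:
                continue
            x = X[i, v]
            if var_angular[v]:
                x = -((-x + 180.0) % 360.0 - 180.0)
            elif clamp_hi[v] == clamp_hi[v]:  # non-nan
                if x < 0.0:
                    x = 0.0
                elif x > clamp_hi[v]:
                    x = clamp_hi[v]
            base = var_start[v]
            for j in range(var_nvals[v]):
                s = base + j
                y = x - shift[s]
                if period[s] != np.inf:
                    y = y % period[s]
                if y < L[s] or y > R[s]:
                    continue
                dl = M[s] - L[s]
                dr = R[s] - M[s]
                left = (y - L[s]) / dl if dl > 0.0 else 1.0
                right = (R[s] - y) / dr if dr > 0.0 else 1.0
                mu = left if left < right else right
                if mu > 1.0:
                    mu = 1.0
                if mu > 0.0:
                    D[i, s] = mu


def degree_table_from_crisp(X: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Population degree table from an (n, 8) crisp-input matrix (columns in
    ``INPUT_VARIABLE_NAMES`` order) and a matching null mask."""
    n = X.shape[0]
    D = np.zeros((n, TABLE_WIDTH))
    if _HAVE_NUMBA:
        _degree_kernel(X, null.astype(np.uint8), _SLOT_L, _SLOT_M, _SLOT_R,
                       _SLOT_SHIFT, _SLOT_PERIOD, _VAR_START, _VAR_NVALS,
                       _VAR_ANGULAR, _VAR_CLAMP_HI, D)
        return D
    for v, name in enumerate(INPUT_VARIABLE_NAMES):
        off = _VAR_OFFSETS[name]
        block = degree_block(name, X[:, v], null[:, v])
        D[:, off:off + block.shape[1]] = block
    return D


@_njit(cache=True)
def _infer_kernel(D, cols, starts, counts, ant_start, owner, cons,
                  curves, lo, hi, w, xw, out):  # pragma: no cover - JIT
    n_agents, G = D.shape[0], curves.shape[1]
    P = np.ones((n_agents, G))
    touched = np.zeros(n_agents, dtype=np.uint8)
    for r in range(starts.shape[0]):
        a = 1.0
        base = ant_start[r]
        o = owner[r]
        for k in range(counts[r]):
            a *= D[o, cols[base + k]]
            if a == 0.0:
                break
        if a <= 0.0:
            continue
        c = cons[r]
        touched[o] = 1
        row = P[o]
        cur = curves[c]
        for i in range(lo[c], hi[c] + 1):
            row[i] *= 1.0 - a * cur[i]
    for o in range(n_agents):
        if touched[o]:
            num = 0.0
            den = 0.0
            row = P[o]
            for i in range(G):
                y = 1.0 - row[i]
                den += y * w[i]
                num += y * xw[i]
            out[o] = num / den if den > 0.0 else 0.0
        else:
            out[o] = 0.0


class PopulationInference:
    """Vectorised inference over many agents, one rule base each.

    The caller supplies a degree table D of shape (n_agents, TABLE_WIDTH)
    holding each agent's membership degree for every (variable, value) slot,
    with whole variable blocks zeroed when the variable is null. Activation,
    probabilistic-sum aggregation and defuzzification are then computed for
    all agents in a handful of array operations.
    """

    def __init__(self, rulebases: Sequence[FuzzyRuleBase], grid: Optional[DefuzzGrid] = None):
        self.grid = grid or _DEFAULT_GRID
        self._rulebases = list(rulebases)
        self._dirty = True

    @property
    def rulebases(self) -> list[FuzzyRuleBase]:
        return self._rulebases

    def replace(self, index: int, rb: FuzzyRuleBase) -> None:
        self._rulebases[index] = rb
        self._dirty = True

    def _rebuild(self) -> None:
        cols, counts, cons, owners = [], [], [], []
        for i, rb in enumerate(self._rulebases):
            c, k, q = compiled(rb)
            cols.append(c)
            counts.append(k)
            cons.append(q)
            owners.append(np.full(len(k), i, dtype=np.int64))
        self._cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
        counts_all = np.concatenate(counts) if counts else np.empty(0, dtype=np.int64)
        self._cons = np.concatenate(cons) if cons else np.empty(0, dtype=np.int64)
        self._owner = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)
        self._counts = counts_all
        self._rule_starts = np.concatenate(([0], np.cumsum(counts_all)[:-1])).astype(np.int64)
        self._ant_owner = np.repeat(self._owner, counts_all)
        self._dirty = False

    def infer(self, degree_table: np.ndarray) -> np.ndarray:
        """Heading change (degrees) for every agent; 0 where no rule fires."""
        if self._dirty:
            self._rebuild()
        n = len(self._rulebases)
        out = np.zeros(n)
        if self._cols.size == 0:
            return out
        if _HAVE_NUMBA:
            g = self.grid
            _infer_kernel(np.ascontiguousarray(degree_table), self._cols,
                          self._rule_starts, self._counts, self._rule_starts,
                          self._owner, self._cons, g.value_curves,
                          g._support_lo, g._support_hi, g._w, g._xw, out)
            return out
        deg = degree_table[self._ant_owner, self._cols]
        act = np.multiply.reduceat(deg, self._rule_starts)
        live = act > 0.0
        if not np.any(live):
            return out
        a = act[live]
        owner = self._owner[live]
        curves_1m = self.grid.value_curves[self._cons[live]]  # copy via fancy index
        curves_1m *= -a[:, None]
        curves_1m += 1.0
        # owners are emitted in ascending order, so segment-reduce per agent
        starts = np.flatnonzero(np.r_[True, owner[1:] != owner[:-1]])
        prod = np.multiply.reduceat(curves_1m, starts, axis=0)
        out[owner[starts]] = self.grid.centroid_rows(1.0 - prod)
        return out


def degree_block(variable: str, x: np.ndarray, null_mask: np.ndarray) -> np.ndarray:
    """Membership degrees of one crisp input column for all of a variable's
    values; rows flagged null are zero (their rules cannot fire)."""
    lv = DATA_BASE[variable]
    safe = np.where(null_mask, 0.0, x)
    block = lv.memberships(safe)
    block[null_mask] = 0.0
    return block


def variable_offset(variable: str) -> int:
    return _VAR_OFFSETS[variable]


# ---------------------------------------------------------------------------
# Serialization, pretty printing, mirroring
# ---------------------------------------------------------------------------

def rulebase_to_dict(rb: FuzzyRuleBase) -> dict:
    return {"rules": [{"if": [[v, n] for v, n in r.antecedents], "then": r.consequent}
                      for r in rb]}


def rulebase_from_dict(data: Mapping) -> FuzzyRuleBase:
    """Build and validate a rule base from its JSON object form."""
    rules = []
    for rec in data["rules"]:
        ants = tuple((str(v), str(n)) for v, n in rec["if"])
        rules.append(FuzzyRule(ants, str(rec["then"])))
    if not rules:
        raise ConfigurationError("rule base must contain at least one rule")
    return FuzzyRuleBase(tuple(rules))


def rulebase_to_json(rb: FuzzyRuleBase) -> str:
    return json.dumps(rulebase_to_dict(rb))


def rulebase_from_json(text: str) -> FuzzyRuleBase:
    return rulebase_from_dict(json.loads(text))


def rule_to_sentence(rule: FuzzyRule) -> str:
    """One linguistic sentence per rule."""
    premise = " AND ".join(f"{var} IS {val}" for var, val in rule.antecedents)
    return f"IF {premise} THEN heading change IS {rule.consequent}"


def rulebase_pretty(rb: FuzzyRuleBase) -> str:
    return "\n".join(rule_to_sentence(r) for r in rb)


_MIRROR_ANGULAR = {"left": "right", "right": "left"}
_MIRROR_OUTPUT = {"hard left": "hard right", "hard right": "hard left",
                  "left": "right", "right": "left"}


def mirror_rule(rule: FuzzyRule) -> FuzzyRule:
    """Swap left and right throughout a rule (reflection of the scene)."""
    ants = []
    for var, val in rule.antecedents:
        if DATA_BASE[var].angular:
            val = _MIRROR_ANGULAR.get(val, val)
        ants.append((var, val))
    return FuzzyRule(tuple(ants), _MIRROR_OUTPUT.get(rule.consequent, rule.consequent))


def mirror_rulebase(rb: FuzzyRuleBase) -> FuzzyRuleBase:
    return FuzzyRuleBase(tuple(mirror_rule(r) for r in rb))
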