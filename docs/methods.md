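# Methods

This note documents the model as implemented, the numerical choices, the
defaults and why they are what they are, and what the test scales do and do
not show.

## World model and conventions

The world is an unbounded 2D plane with a square living area (side 375
distance units) centred at the origin; distances and update steps are in
arbitrary units. Headings are degrees; heading h moves the agent along
(cos h, sin h). Relative bearing is the wrapped signed difference between the
direction to a target and the agent's heading, in (−180°, 180°]: 0 dead
ahead, negative on the agent's left, so a positive heading change is a right
turn. Under this convention a whole-scene reflection (y → −y, h → −h,
left/right value names swapped in every rule) reproduces the mirrored
trajectory exactly, which the tests exploit.

Updates are synchronous. Per step: (1) every agent's perception and desired
heading change are computed from the pre-step state; (2) headings are updated
by the full defuzzified change — no turn-rate cap, since the output is
already bounded by the output universe — and positions advance at constant
speed (prey 2, single-target predators 3, high-density-area predators 1.5);
(3) energy accounting: +1 foraging gain per prey, −10 once per step for a
prey in contact with any other prey (centre distance below the sum of the two
body radii), −10 per step spent outside the living area; (4) captures;
(5) every dead prey is replaced in the same step, so the population size is
invariant; (6) predator hunt/re-entry timers advance.

All randomness flows through one seeded NumPy generator in a fixed order per
step (interaction draws, replacement draws per dead slot in ascending slot
order, predator re-entry draws in predator order), so a run is bit-for-bit
reproducible from its seed.

Perception is gated by distance only (no occlusion or blind angle): prey
perceive conspecifics, predators and the living-area border point within 100
units; any group of inputs beyond that range is null, and a null variable
vetoes every rule that mentions it. The interaction partner is a single
conspecific sampled per step with weight 1/max(d, ε), ε = 10⁻⁶. Newborn prey
spawn uniformly on the 325-radius disc with uniform headings; because the
spawn radius exceeds the living-area half-side (187.5), newborns can legally
appear outside the square — that is the printed parameterisation, kept as-is.

Predator tactics: "nearest" and "most central" (nearest to the centroid of
perceived prey, following the selfish-herd literature's geometry) and "most
isolated" (largest nearest-neighbour distance) hold a single target until it
is captured or dies; the high-density-area tactic re-aims every step at the
prey with the most conspecifics within its catch radius and captures
everything inside that radius. The pursuit controller of the predator is a
preset four-rule base through the same inference engine: bearing left → turn
left, in front → none, right → right, behind → hard right. The behind rule is
deliberately chiral: it resolves the dead-behind deadlock, at the cost of
exact mirror antisymmetry of pursuit within ±90° of dead-behind.

## Fuzzy inference

Membership functions are triangular fuzzy numbers; a zero-width side (e.g.
⟨0, 0, 10⟩, ⟨60, 100, 100⟩) is a crisp shoulder with membership 1 on the
degenerate boundary, matching the intent of the data base's edge values.
Periodic values ("behind", "opposite") are evaluated as a plain triangle on
the wrapped coordinate y = (x − l) mod c, which keeps membership in [0, 1]
for all inputs and is invariant under x → x + c. Distance inputs are clamped
to [0, 100] before evaluation ("far" is flat at its peak beyond its support).

Inference: rule activation is the product of antecedent memberships (exactly
0 if any antecedent variable is null); each consequent triangle is scaled by
its activation (product implication) and the scaled curves are combined
pointwise with the probabilistic sum; the crisp output is the centre of
gravity of the aggregate, computed by trapezoidal quadrature on a uniform
grid over [−180°, 180°].

Grid resolution defaults to 0.25° (1441 points): it reproduces the worked
example's printed output (54.375°) to better than 0.01° — verified in the
tests against an independent quadrature oracle on a 10× finer grid — and is
cheap. The resolution is configurable. When no rule fires the aggregate is
identically zero and the defuzzified output is defined as 0 (no turn), the
neutral action.

Two implementations of the pipeline coexist and are tested against each
other to 10⁻⁹ degrees: a scalar reference path (used by the public
`infer_heading_change` and in all worked-example checks) and a vectorised
population path that fuzzifies all prey inputs into a degree table and
evaluates every rule of every agent in a few array operations (JIT-compiled
when numba is available, pure NumPy otherwise). The predator's fixed pursuit
controller, a pure function of target bearing, is tabulated on a dense
bearing grid and linearly interpolated; the interpolation error is below
10⁻³ degrees, also asserted in the tests.

## Evolution

Fitness is the prey's energy at the moment a replacement is made — the
survivability currency of the model — with no age bonus. Parents are two
distinct survivors of the current step, drawn without replacement with
probability proportional to energy. Crossover picks a uniform random length
in [1, min(|joint|, 50)] and samples rules uniformly without replacement from
the parents' concatenated rule multiset (a with-replacement switch exists for
sensitivity analysis). Mutation fires once per offspring with probability
0.02 and chooses add or remove with equal probability ("either … or" read as
symmetric); additions are 1–3 fresh fully random rules truncated at the
50-rule bound, removals 1–3 uniformly chosen rules never reducing the base
below one rule. Random rules draw their antecedent count uniformly from 1–4,
variables without replacement, and values and consequents uniformly.

Open choices resolved here: mutation cannot fire twice on one offspring, add
and remove cannot co-occur, and parents are always distinct agents; an
offspring has at least one rule (an empty chromosome would be a non-agent,
though the container type tolerates emptiness as a null controller for
testing). Newborns receive the full initial energy and a uniform heading.

## Validation protocol and metrics

`run_validation` replays an evolved pool with evolution off: per replicate,
prey are scattered on the spawn disc with pool-sampled rule bases, the scene
stabilises for 900 steps, metrics are recorded to step 1800 predator-free,
then one predator (tactic drawn uniformly per replicate; configurable) enters
at exactly step 1800 and recording continues to step 3600. Dead prey are
replaced by agents drawn uniformly from the pool — the replacement rule when
evolution is off is not otherwise constrained, and uniform pool sampling
keeps the replayed behaviour representative. Default 20 replicates.

Group structure uses strict inequality (distance < perception) for edges,
consistent with perception gating; singletons are stragglers and excluded
from local-scale metrics, while global polarization/rotation treat the whole
population as one group, stragglers included. An agent exactly on its group
centroid contributes zero to rotation (its radial unit vector is undefined).
Time-in-state proportions split each step's unit weight equally across that
step's groups; steps with no groups reduce the denominator. Bootstrap CIs are
percentile intervals over 10,000 resamples by default. The behaviour class of
a run is the argmax state-time label, reported as D (dynamic) when transition
dominates.

Local density is the count of conspecifics strictly within a radius
(default: the prey perception distance, 100), averaged over all prey. The
measure is a plug-in: the literature it descends from does not pin down a
single formula, and the choice matters — see limitations.

## Rule-base statistics

Attention proportions ρ_α average, per rule, the fraction of antecedents
referring to the living area, the nearest predator, or the interacting prey;
they sum to 1 and equal (2/8, 3/8, 3/8) for a base with one single-antecedent
rule per input variable. Specificity is the mean of (aᵢ − 1)/(m − 1) with
m = 4. Bias is (1/2n) Σ (1 + oᵢ/180) where oᵢ is the geometric centroid
(l + m + r)/3 of the consequent triangle — ±150 for the "hard" shoulder
values, the peak for the symmetric ones; mirroring a rule base maps β to
1 − β. Size is the rule count over the 50-rule bound.

## Problem sizes used in the tests

The model's reference experimental design is 20 evolutions of 10⁷ steps each;
that is far beyond a test suite, so the suite works at reduced scale as its own study
design: unit and property tests use worlds of 10–40 agents over 10²–10³
steps, and the evolutionary density contrast runs 5 predator-present and 5
predator-free evolutions of 5 × 10⁴ steps with the full 100-prey world.
Scripted scenes (parallel lattice, tangential ring, uniform blob) exercise
the classifier without any evolution.

## Known limitations

- At 5 × 10⁴ steps, selection has reliably fixed "stay inside the living
  area" but not the collision-avoidance/spreading that emerges over full-length
  (10⁷-step) runs. With the neighbour-count density measure, merely compacting from
  the 325-radius spawn disc into the 375-side square raises mean local
  density several-fold; predator-free control populations therefore show a
  *larger* density rise at this scale than predator-present ones (predation
  actively removes and disperses clustered prey). The predation-increase
  direction reproduces; the predator-free "no grouping" contrast does not
  emerge at this scale — the corresponding check is left failing rather than
  redefined, and the per-seed numbers are in the test output.
- No neighbour-count-at-a-fixed-radius measure can reproduce the full-scale
  control-run density *decrease*: uniform spreading inside the square gives a
  higher radius-100 count than the initial disc scatter. Reported full-scale
  density values evidently rest on a finer-scaled measure that is not fully
  specified; the measure here is deliberately pluggable.
- The predator pursuit controller is a minimal documented design: four
  bearing rules through the shared inference engine. Richer preset pursuit
  controllers exist in earlier related systems but are not specified here.
- Perception has no occlusion, no field-of-view limit, no noise; speeds are
  constant; the world is planar. These are modelling assumptions inherited
  from the original design, not simplifications of it.
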