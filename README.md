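# fuzzyflock

Evolution of collective prey behaviour in a 2D artificial world where every
prey agent is steered by its own **linguistic fuzzy rule-based system** and
predation supplies the only selection pressure.

The package is aimed at researchers in computational ethology and artificial
life who want a bottom-up evolutionary model of flocking: instead of tuning
the weights of pre-designed drives (cohesion, separation, alignment), each
prey agent carries a human-readable chromosome — an IF-THEN rule base over a
fixed fuzzy data base — and survival alone decides which rule bases persist.
Evolved populations display the three classes of collective motion known from
fish schools (swarming, milling, polarized) plus dynamic transitions between
them.

## The model

**Agents.** Prey (n = 100, speed 2, perception distance 100) live inside a
square living area (side 375) centred in an open plane. Each update step a
prey agent perceives up to eight nullable crisp inputs: distance, relative
bearing and relative heading of one interacting conspecific (sampled with
probability inversely proportional to distance), the same for the nearest
predator, and distance plus bearing of the closest living-area border point.
Predators (16, in two morphs) cycle between off-world waiting and 600-step
hunts, entering on a circle of radius 400 with one of four target-selection
tactics: nearest, most isolated, most central (single-target) or high-density
area attack (captures every prey within its catch radius).

**Controller.** Inputs are singleton fuzzy values over the fixed data base of
triangular fuzzy numbers ⟨l, m, r⟩ (periodic ⟨l, m, r⟩₃₆₀ for "behind"/
"opposite"). A rule base is 1–50 rules, each with 1–4 antecedents over
distinct variables and one consequent among five heading-change values.
Inference is Mamdani-style: product t-norm for conjunction and implication,
probabilistic sum (x ◇ y = x + y − xy) for aggregation, centre-of-gravity
defuzzification of the aggregated curve on [−180°, 180°].

**Evolution.** Steady-state and open-ended: a prey that is captured or runs
out of energy (foraging gain +1 per step, −10 per collision, −10 per step
outside the living area) is replaced immediately. Two parents are selected
with probability proportional to energy; the offspring's rule base is drawn
uniformly without replacement from the parents' joint rule multiset at a
random length (Pittsburgh scheme, messy variable-length coding), then mutated
with probability 0.02 (add or remove 1–3 rules).

**Metrics.** Groups are connected components of the mutual-perception graph.
For a group of n agents with unit velocities v̂ᵢ and unit centroid-offsets ĉᵢ:

- polarization p = ‖(1/n) Σ v̂ᵢ‖,
- rotation m = |(1/n) Σ ĉᵢ × v̂ᵢ|,

classified as polar (P: p > 0.65, m < 0.35), milling (M: p < 0.35, m > 0.65),
swarming (S: both < 0.35) or transitional (T) otherwise. Rule bases are
summarised by six parameters: attention proportions ρ_living/ρ_predator/
ρ_prey, specificity ς = mean (aᵢ−1)/(m−1), turning bias
β = (1/2n) Σ (1 + oᵢ/180), and relative size.

## Worked example

The reference inference scene: one prey heading along +x, the nearest
predator at distance 50 and relative bearing −126°, and the two-rule base
*{IF predator bearing IS left THEN turn right; IF predator bearing IS behind
THEN no turn}*:

```python
>>> from fuzzyflock import (DATA_BASE, InputVector, infer_heading_change,
...                         tri_membership, make_fig1_scene)
>>> left = DATA_BASE["predator.relative_bearing"].fuzzy_set("left")
>>> tri_membership(-126.0, left)
0.6
>>> scene = make_fig1_scene()
>>> iv = InputVector(predator_distance=50.0, predator_bearing=-126.0,
...                  predator_heading=54.0)
>>> round(infer_heading_change(scene.rulebase, iv), 3)
54.375
```

The antecedent "bearing is left" holds to degree 0.6 (and "behind" to 0.4);
scaling the consequent triangles by those activations, aggregating with the
probabilistic sum and taking the centre of gravity yields a desired heading
change of 54.375° — the prey turns right, away from the predator.

A small evolutionary run from the shell:

```sh
fuzzyflock evolve --seed 1 --steps 50000 --out runs/demo
fuzzyflock validate runs/demo/pool.json --seed 1 --out validation/demo
fuzzyflock rulestats runs/demo/pool.json --out rulestats.csv
```

`evolve` writes the evolved pool (JSON), a periodic metric log and an event
log; `validate` replays the pool without evolution (20 replicates, predator
introduced at step 1800) and reports state-time proportions with bootstrap
CIs; `rulestats` exports the six-parameter summary table.

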