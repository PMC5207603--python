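"""Geometry, perception, predator tactics and the synchronous update loop."""

import numpy as np
import pytest

from fuzzyflock import fuzzy as F
from fuzzyflock import world as W
from fuzzyflock.evolution import random_rulebase


class TestGeometry:
    @pytest.mark.parametrize("pos,heading,target,expected", [
        ((0, 0), 0.0, (10, 0), 0.0),       # dead ahead
        ((0, 0), 0.0, (0, -10), -90.0),    # 90 degrees to the left
        ((0, 0), 0.0, (0, 10), 90.0),      # 90 degrees to the right
        ((0, 0), 0.0, (-10, 0), 180.0),    # directly behind
        ((0, 0), 90.0, (10, 0), -90.0),
    ])
    def test_bearing_convention(self, pos, heading, target, expected):
        assert W.relative_bearing(pos, heading, target) == pytest.approx(expected)

    def test_bearing_coincident_points_error(self):
        with pytest.raises(ValueError):
            W.relative_bearing((1, 1), 0.0, (1, 1))

    def test_bearing_mirror_antisymmetry(self, rng):
        for _ in range(50):
            pos = rng.uniform(-100, 100, 2)
            target = rng.uniform(-100, 100, 2)
            if np.allclose(pos, target):
                continue
            h = float(rng.uniform(-179, 180))
            b = W.relative_bearing(pos, h, target)
            bm = W.relative_bearing(pos * (1, -1), -h, target * (1, -1))
            if abs(abs(b) - 180.0) > 1e-9:  # dead-behind wraps to +180 both ways
                assert bm == pytest.approx(-b, abs=1e-9)

    @pytest.mark.parametrize("own,other,expected", [
        (45.0, 45.0, 0.0),
        (0.0, 180.0, 180.0),
        (90.0, 0.0, -90.0),
        (-170.0, 170.0, -20.0),
    ])
    def test_relative_heading(self, own, other, expected):
        assert W.relative_heading(own, other) == pytest.approx(expected)

    @pytest.mark.parametrize("pos,expected_point,expected_dist", [
        ((100, 0), (187.5, 0), 87.5),
        ((0, 0), (187.5, 0), 187.5),                      # tie broken to +x
        ((300, 300), (187.5, 187.5), np.hypot(112.5, 112.5)),  # outside corner
        ((0, -150), (0, -187.5), 37.5),
    ])
    def test_closest_border_point(self, pos, expected_point, expected_dist):
        point, dist = W.closest_border_point(pos, 375.0)
        assert point == pytest.approx(expected_point)
        assert dist == pytest.approx(expected_dist)

    def test_closest_border_point_vs_dense_perimeter(self, rng):
        side = 375.0
        half = side / 2
        t = np.linspace(0, 1, 4001)[:-1]
        edge = np.concatenate([
            np.stack([np.full_like(t, half), -half + side * t], 1),
            np.stack([-half + side * t, np.full_like(t, half)], 1),
            np.stack([np.full_like(t, -half), -half + side * t], 1),
            np.stack([-half + side * t, np.full_like(t, -half)], 1)])
        for _ in range(40):
            p = rng.uniform(-300, 300, 2)
            _, dist = W.closest_border_point(p, side)
            brute = np.hypot(*(edge - p).T).min()
            assert dist == pytest.approx(brute, abs=0.2)


class TestPerception:
    def test_partner_sampling_none_in_range(self, rng):
        others = np.array([[500.0, 0.0], [0.0, 800.0]])
        assert W.sample_interaction_partner((0, 0), None, others, 100.0, rng) is None

    def test_partner_sampling_single_neighbour(self, rng):
        others = np.array([[0.0, 0.0], [30.0, 0.0]])
        for _ in range(10):
            assert W.sample_interaction_partner((0, 0), 0, others, 100.0, rng) == 1

    def test_partner_sampling_inverse_distance_weights(self, rng):
        # neighbours at 25 and 75 -> odds 3:1
        others = np.array([[0.0, 0.0], [25.0, 0.0], [0.0, 75.0]])
        n = 30_000
        picks = np.array([W.sample_interaction_partner((0, 0), 0, others, 100.0, rng)
                          for _ in range(n)])
        assert np.mean(picks == 1) == pytest.approx(0.75, abs=0.012)
        assert np.mean(picks == 2) == pytest.approx(0.25, abs=0.012)

    def _world_with_predator(self, prey_pos, prey_heading, pred_pos, n_predators=1):
        cfg = W.WorldConfig(n_prey=len(prey_pos), n_predators=n_predators, seed=0)
        rbs = [F.FuzzyRuleBase(()) for _ in prey_pos]
        world = W.World(cfg, rbs, rng=np.random.default_rng(0))
        world.prey_pos = np.asarray(prey_pos, float)
        world.prey_heading = np.asarray(prey_heading, float)
        if n_predators:
            world.predators[0].on_world = True
            world.predators[0].position = np.asarray(pred_pos, float)
        return world

    def test_predator_beyond_perception_is_null(self, rng):
        world = self._world_with_predator([[0, 0]], [0.0], [150.0, 0.0])
        iv = W.build_perception(world, 0, rng)
        assert iv.predator_distance is None

    def test_border_beyond_perception_is_null(self, rng):
        world = self._world_with_predator([[0, 0]], [0.0], [0, 0], n_predators=0)
        iv = W.build_perception(world, 0, rng)
        assert iv.area_distance is None  # centre is 187.5 from the border

    def test_border_within_perception(self, rng):
        world = self._world_with_predator([[100, 0]], [0.0], [0, 0], n_predators=0)
        iv = W.build_perception(world, 0, rng)
        assert iv.area_distance == pytest.approx(87.5)
        assert iv.area_bearing == pytest.approx(0.0)

    def test_worked_scene_bearing(self, rng):
        ang = np.radians(-126.0)
        pred = 50.0 * np.array([np.cos(ang), np.sin(ang)])
        world = self._world_with_predator([[0, 0]], [0.0], pred)
        iv = W.build_perception(world, 0, rng)
        assert iv.predator_bearing == pytest.approx(-126.0)


class TestPredatorTactics:
    def _pred(self, tactic, pos=(0.0, 0.0)):
        return W.PredatorState(0, tactic, np.asarray(pos, float), 0.0, on_world=True)

    def test_nearest(self):
        prey = np.array([[50.0, 0], [80.0, 0], [120.0, 0]])
        cfg = W.WorldConfig(n_prey=3)
        assert W.select_target(self._pred("nearest"), prey, cfg) == 0

    def test_most_isolated(self):
        prey = np.array([[0.0, 0], [5.0, 0], [0.0, 5], [200.0, 0]])
        cfg = W.WorldConfig(n_prey=4)
        assert W.select_target(self._pred("most_isolated"), prey, cfg) == 3

    def test_most_central(self):
        th = np.linspace(0, 2 * np.pi, 9)[:-1]
        ring = 50 * np.stack([np.cos(th), np.sin(th)], 1)
        prey = np.vstack([ring, [[0.0, 0.0]]])
        cfg = W.WorldConfig(n_prey=9)
        assert W.select_target(self._pred("most_central"), prey, cfg) == 8

    def test_hda_returns_densest_point(self):
        clump = np.array([[0.0, 0], [3.0, 0], [0.0, 3], [-3.0, 0]])
        lone = np.array([[100.0, 100.0]])
        prey = np.vstack([clump, lone])
        cfg = W.WorldConfig(n_prey=5)
        point = W.select_target(self._pred("hda"), prey, cfg)
        assert np.allclose(point, [0.0, 0.0])  # most neighbours within catch=12

    def test_no_prey_in_perception(self):
        prey = np.array([[1000.0, 0.0]])
        cfg = W.WorldConfig(n_prey=1)
        assert W.select_target(self._pred("nearest"), prey, cfg) is None

    def test_pursuit_dead_ahead_no_turn(self):
        pred = self._pred("nearest")
        assert W.predator_step(pred, (50.0, 0.0), 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_pursuit_mirror_antisymmetry_ahead(self):
        """Reflection negates the turn wherever the asymmetric dead-behind
        rule (behind -> hard right) does not fire, i.e. |bearing| < 90."""
        pred = self._pred("nearest")
        for ang in (-80.0, -40.0, 10.0, 30.0, 75.0):
            rad = np.radians(ang)
            tgt = 50 * np.array([np.cos(rad), np.sin(rad)])
            a = W.predator_step(pred, tgt, 0.0)
            b = W.predator_step(pred, tgt * (1, -1), 0.0)
            assert a == pytest.approx(-b, abs=1e-9)

    def test_pursuit_dead_behind_breaks_deadlock_to_the_right(self):
        pred = self._pred("nearest")
        assert W.predator_step(pred, (-50.0, 0.0), 0.0) > 90.0

    def test_fast_controller_matches_inference(self):
        grid = F.default_grid()
        pred = self._pred("nearest")
        pred.heading = 33.0
        for ang in np.linspace(-170, 179, 23):
            rad = np.radians(ang)
            tgt = 60 * np.array([np.cos(rad), np.sin(rad)])
            assert W.pursuit_turn(pred, tgt, grid) == pytest.approx(
                W.predator_step(pred, tgt, 0.0, grid), abs=1e-3)


def _quiet_world(n=10, spacing=50.0, rulebases=None, **cfg_overrides):
    """Spread-out prey inside the living area, no predators by default."""
    cfg = W.WorldConfig(n_prey=n, n_predators=0, seed=3, **cfg_overrides)
    rbs = rulebases or [F.FuzzyRuleBase(()) for _ in range(n)]
    world = W.World(cfg, rbs, rng=np.random.default_rng(3), log_events=True)
    cols = int(np.ceil(np.sqrt(n)))
    idx = np.arange(n)
    world.prey_pos = np.stack([(idx % cols) * spacing - 80,
                               (idx // cols) * spacing - 80], axis=1).astype(float)
    world.prey_heading = np.zeros(n)
    return world


class TestStepWorld:
    def test_foraging_gain_only(self):
        world = _quiet_world()
        world.step()
        assert np.allclose(world.prey_energy, 1001.0)

    def test_null_rulebases_move_straight(self):
        world = _quiet_world()
        start = world.prey_pos.copy()
        for _ in range(10):
            world.step()
        assert np.allclose(world.prey_heading, 0.0)
        assert np.allclose(world.prey_pos, start + [20.0, 0.0])

    def test_collision_death_and_replacement(self):
        world = _quiet_world(n=2)
        world.prey_pos = np.array([[0.0, 0.0], [1.0, 0.0]])  # within 2*size
        world.prey_energy[:] = 5.0
        world.step()
        # 5 + 1 - 10 <= 0 -> both replaced, population conserved
        assert world.counts["death"] == 2
        assert world.counts["birth"] == 2
        assert len(world.prey_pos) == 2
        assert np.all(world.prey_energy == 1000.0)

    def test_wandering_penalty_applied_each_step_outside(self):
        world = _quiet_world(n=1)
        world.prey_pos = np.array([[300.0, 300.0]])
        world.step()
        world.step()
        assert world.prey_energy[0] == pytest.approx(1000.0 + 2 * (1.0 - 10.0))
        assert world.prey_wanders[0] == 2

    def test_population_conserved_and_finite(self, small_world_factory):
        world = small_world_factory(n_prey=30, n_predators=4,
                                    re_enter_low=5, re_enter_high=10,
                                    hunt_duration=20, initial_energy=40.0)
        for _ in range(300):
            world.step()
            assert len(world.prey_pos) == 30
            assert np.isfinite(world.prey_pos).all()
        assert world.counts["death"] == world.counts["birth"]
        assert world.counts["death"] > 0  # the run actually exercised turnover

    def test_energy_ledger_balances(self, small_world_factory):
        world = small_world_factory(n_prey=25, n_predators=2,
                                    re_enter_low=5, re_enter_high=8)
        for _ in range(400):
            world.step()
        cfg = world.cfg
        alive_steps = world.step_count - world.prey_birth
        expected = (cfg.initial_energy + cfg.foraging_gain * alive_steps
                    + cfg.collision_penalty * world.prey_collisions
                    + cfg.wandering_penalty * world.prey_wanders)
        assert np.allclose(world.prey_energy, expected)

    def test_predator_count_never_exceeds_config(self, small_world_factory):
        world = small_world_factory(n_prey=20, n_predators=3,
                                    re_enter_low=3, re_enter_high=6, hunt_duration=10)
        for _ in range(100):
            world.step()
            assert len(world.predators) == 3
            on = [p for p in world.predators if p.on_world]
            for p in on:
                assert np.hypot(*p.position) < 1e4

    def test_predator_enters_after_initial_countdown(self, small_world_factory):
        world = small_world_factory(n_prey=20, n_predators=2,
                                    re_enter_low=3, re_enter_high=5, hunt_duration=7)
        seen_on_world = 0
        for _ in range(20):
            world.step()
            seen_on_world += sum(p.on_world for p in world.predators)
        assert seen_on_world > 0
        # entry pose: on the ambush circle heading toward the centre
        world2 = small_world_factory(n_prey=5, n_predators=1,
                                     re_enter_low=1, re_enter_high=1)
        world2.step()
        p = world2.predators[0]
        assert p.on_world
        assert np.hypot(*p.position) == pytest.approx(world2.cfg.ambush_distance)
        b = W.relative_bearing(p.position, p.heading, (0.0, 0.0))
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_capture_replaces_target(self):
        cfg = W.WorldConfig(n_prey=3, n_predators=1, seed=0)
        rbs = [F.FuzzyRuleBase(()) for _ in range(3)]
        world = W.World(cfg, rbs, rng=np.random.default_rng(0), log_events=True)
        world.prey_pos = np.array([[10.0, 0.0], [80.0, 0.0], [0.0, 80.0]])
        world.prey_heading = np.zeros(3)
        p = world.predators[0]
        p.on_world = True
        p.tactic = "nearest"
        p.position = np.array([8.0, 0.0])
        p.steps_remaining = 100
        world.step()
        assert world.counts["capture"] == 1
        assert world.counts["birth"] == 1

    def test_mirror_symmetry_of_trajectories(self, rng):
        """Reflecting the scene, headings and rule bases reflects the run."""
        n = 12
        gen = np.random.default_rng(42)
        rbs = [random_rulebase(gen, max_rules=6) for _ in range(n)]
        pos = gen.uniform(-120, 120, (n, 2))
        head = gen.uniform(-179, 179, n)

        def run(positions, headings, rulebases, steps=40):
            cfg = W.WorldConfig(n_prey=n, n_predators=0, seed=9)
            world = W.World(cfg, rulebases, rng=np.random.default_rng(9))
            world.prey_pos = positions.copy()
            world.prey_heading = headings.copy()
            traj = []
            for _ in range(steps):
                world.step()
                traj.append(world.prey_pos.copy())
            return np.array(traj)

        direct = run(pos, head, rbs)
        mirrored = run(pos * (1, -1), -head, [F.mirror_rulebase(rb) for rb in rbs])
        assert np.allclose(mirrored, direct * (1, -1), atol=1e-8)
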