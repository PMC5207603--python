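import numpy as np
import pytest

from fuzzyflock.evolution import random_rulebase
from fuzzyflock.world import World, WorldConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_world_factory():
    """Worlds small enough for per-step assertions but with full dynamics."""

    def make(n_prey=20, n_predators=2, seed=7, **overrides):
        cfg = WorldConfig(n_prey=n_prey, n_predators=n_predators, seed=seed,
                          **overrides)
        gen = np.random.default_rng(seed)
        rbs = [random_rulebase(gen) for _ in range(n_prey)]
        world = World(cfg, rbs, rng=gen, log_events=True)
        world.scatter_prey()
        return world

    return make
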