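import numpy as np
import pytest

from capsim import (
    MembraneDynamics,
    SimulationConfig,
    Stimulus,
    StimulusLabel,
    StimulusSchedule,
    generate_binary_tree,
    generate_collision_edge,
    generate_ladder,
)

US = 1e-6
MS = 1e-3


@pytest.fixture
def default_dynamics():
    return MembraneDynamics()


@pytest.fixture
def fast_refractory():
    """Short refractory tail so PASS-after-window cases fit small graphs."""
    return MembraneDynamics(refractory_s=20 * US)


@pytest.fixture
def collision_edge():
    return generate_collision_edge(100.0)


def assert_conserved(log):
    c = log.counters
    total = (c["exited"] + c["annihilated"] + c["annulled"]
             + c["merged"] + c["failed"] + c["active"])
    assert c["spawned"] == total, f"conservation violated: {c}"


def random_scenario(seed):
    """A small randomized network + stimulus schedule for engine/oracle
    cross-checks.  Graphs stay at or below ~10 nodes; stimulus times are
    continuous so event times are generic (no accidental ties)."""
    rng = np.random.default_rng(seed)
    dyn = MembraneDynamics(
        refractory_s=float(rng.choice([100 * US, 500 * US, 2 * MS])),
    )
    kind = rng.integers(3)
    if kind == 0:
        g = generate_ladder(
            n_layers=int(rng.integers(1, 3)),
            n_parallel=int(rng.integers(2, 4)),
            segment_length_um=float(rng.uniform(60, 150)),
            dynamics=dyn,
            jitter_sd_um=float(rng.uniform(0, 5)),
            seed=int(rng.integers(2**31)),
        )
        entries = ["entry"]
    elif kind == 1:
        g = generate_collision_edge(float(rng.uniform(60, 150)), dyn)
        entries = ["A", "B"]
    else:
        g = generate_binary_tree(2, float(rng.uniform(60, 150)), dyn)
        entries = ["root"]
    stimuli = []
    for node in entries:
        for _ in range(int(rng.integers(1, 3))):
            stimuli.append(
                Stimulus(float(rng.uniform(0, 400 * US)), node,
                         StimulusLabel.SIGNAL)
            )
    schedule = StimulusSchedule(stimuli).sorted()
    horizon = 5 * MS
    dt = 2 * US
    return g, schedule, horizon, dt


@pytest.fixture
def sim_config():
    return SimulationConfig()
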