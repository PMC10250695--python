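import numpy as np
import pytest

from arbitrl import (
    AgentSpec,
    DecisionTree,
    generate_schedule,
    generate_tree,
    simulate_session,
)


@pytest.fixture(scope="session")
def tree():
    return generate_tree(1)


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(2)


@pytest.fixture(scope="session")
def mb_session(tree, schedule):
    """A pure-MB simulated session on the shared tree/schedule."""
    agent = AgentSpec(kind="pure_mb", mb_params=(0.4, 0.2), agent_seed=3)
    return simulate_session(tree, schedule, agent)


@pytest.fixture(scope="session")
def mf_session(tree, schedule):
    agent = AgentSpec(kind="pure_mf", mf_params=(0.3, 0.15), agent_seed=4)
    return simulate_session(tree, schedule, agent)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_tree():
    """Hand-built 1-2-4 tree for arithmetic checks.

    Terminals: 3=blue/40, 4=gray/0, 5=yellow/10, 6=red/20.
    """
    return DecisionTree(
        n_stage2=2,
        n_stage3=4,
        successors={
            (0, 0): (1, 2), (0, 1): (2, 1),
            (1, 0): (3, 4), (1, 1): (4, 3),
            (2, 0): (5, 6), (2, 1): (6, 5),
        },
        terminal_value={3: 40, 4: 0, 5: 10, 6: 20},
        terminal_color={3: "blue", 4: "gray", 5: "yellow", 6: "red"},
        tree_seed=-1,
    )
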