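"""Two-choice, three-stage Markov decision environment.

States are 0-based integers grouped by stage: state 0 is the root
(stage 1), states ``1..n_stage2`` form stage 2, and the remaining
``n_stage3`` states are terminal (stage 3).  Actions are coded
``0 = left``, ``1 = right``.  Every non-terminal (state, action) pair has
exactly two candidate successors; under low transition uncertainty the
first ("likely") candidate is reached with probability 0.9, under high
uncertainty with probability 0.5.

Terminal states carry colored coin values: gray = 0, yellow = 10,
red = 20, blue = 40.  In the *flexible* condition every coin pays out;
in the *specific* condition only the cued goal color pays out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

ACTIONS = (0, 1)
COLORS = ("gray", "yellow", "red", "blue")
COLOR_VALUE = {"gray": 0, "yellow": 10, "red": 20, "blue": 40}
GOAL_COLORS = ("yellow", "red", "blue")
CONDITIONS = ("specific", "flexible")
UNCERTAINTIES = ("low", "high")

#: probability of reaching the designated likely successor
LIKELY_P = {"low": 0.9, "high": 0.5}

DEFAULT_TERMINAL_LABELS = (
    "gray", "gray", "yellow", "yellow", "red", "red", "blue", "blue",
)


@dataclass(frozen=True)
class TopologyConfig:
    """Shape of the decision tree: stage sizes and terminal coin labels."""

    n_stage2: int = 4
    n_stage3: int = 8
    terminal_labels: tuple[str, ...] = DEFAULT_TERMINAL_LABELS

    def __post_init__(self) -> None:
        if self.n_stage2 < 2 or self.n_stage3 < 2:
            raise ValueError("stages 2 and 3 need at least two states each")
        if len(self.terminal_labels) != self.n_stage3:
            raise ValueError(
                f"{len(self.terminal_labels)} terminal labels for "
                f"{self.n_stage3} terminal states"
            )
        unknown = set(self.terminal_labels) - set(COLORS)
        if unknown:
            raise ValueError(f"unknown coin colors: {sorted(unknown)}")
        missing = set(GOAL_COLORS) - set(self.terminal_labels)
        if missing:
            raise ValueError(
                "terminal labels must include every goal color; missing: "
                f"{sorted(missing)} (specific goals would be unattainable)"
            )


@dataclass(frozen=True)
class DecisionTree:
    """Subject-specific task graph with candidate successors and coin labels.

    ``successors[(state, action)]`` is an ordered pair of next-stage state
    ids; the first entry is the likely successor under low uncertainty.
    """

    n_stage2: int
    n_stage3: int
    successors: dict[tuple[int, int], tuple[int, int]]
    terminal_value: dict[int, int]
    terminal_color: dict[int, str]
    tree_seed: int

    @property
    def root(self) -> int:
        return 0

    @property
    def n_states(self) -> int:
        return 1 + self.n_stage2 + self.n_stage3

    @property
    def stage2_states(self) -> range:
        return range(1, 1 + self.n_stage2)

    @property
    def stage3_states(self) -> range:
        return range(1 + self.n_stage2, self.n_states)

    def stage_of(self, state: int) -> int:
        if state == 0:
            return 1
        if state <= self.n_stage2:
            return 2
        return 3

    def is_terminal(self, state: int) -> bool:
        return state > self.n_stage2

    def nonterminal_states(self) -> list[int]:
        return [0, *self.stage2_states]

    def validate(self) -> None:
        for s in self.nonterminal_states():
            for a in ACTIONS:
                pair = self.successors.get((s, a))
                if pair is None or len(pair) != 2:
                    raise ValueError(f"({s}, {a}) must have exactly 2 successors")
                want_stage = self.stage_of(s) + 1
                for nxt in pair:
                    if self.stage_of(nxt) != want_stage:
                        raise ValueError(
                            f"successor {nxt} of ({s}, {a}) not in stage {want_stage}"
                        )
        for t in self.stage3_states:
            color = self.terminal_color[t]
            value = self.terminal_value[t]
            if COLOR_VALUE[color] != value:
                raise ValueError(f"terminal {t}: color {color} != value {value}")
        reach = self.reachable_colors()
        if not set(GOAL_COLORS) <= reach:
            raise ValueError(f"goal colors unreachable: {set(GOAL_COLORS) - reach}")

    def reachable_colors(self) -> set[str]:
        reachable2 = {s for a in ACTIONS for s in self.successors[(0, a)]}
        reachable3 = {
            s for s2 in reachable2 for a in ACTIONS for s in self.successors[(s2, a)]
        }
        return {self.terminal_color[t] for t in reachable3}

    def to_dict(self) -> dict:
        return {
            "n_stage2": self.n_stage2,
            "n_stage3": self.n_stage3,
            "successors": {f"{s},{a}": list(v) for (s, a), v in self.successors.items()},
            "terminal_value": {str(k): v for k, v in self.terminal_value.items()},
            "terminal_color": {str(k): v for k, v in self.terminal_color.items()},
            "tree_seed": self.tree_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        successors = {}
        for key, val in d["successors"].items():
            s, a = (int(x) for x in key.split(","))
            successors[(s, a)] = (int(val[0]), int(val[1]))
        tree = cls(
            n_stage2=int(d["n_stage2"]),
            n_stage3=int(d["n_stage3"]),
            successors=successors,
            terminal_value={int(k): int(v) for k, v in d["terminal_value"].items()},
            terminal_color={int(k): str(v) for k, v in d["terminal_color"].items()},
            tree_seed=int(d["tree_seed"]),
        )
        tree.validate()
        return tree


def generate_tree(tree_seed: int, config: TopologyConfig | None = None) -> DecisionTree:
    """Draw a random decision tree; identical seed and config give an
    identical tree.  Trees are redrawn until every goal color is reachable
    from the root, so the specific condition is always solvable."""
    config = config or TopologyConfig()
    rng = np.random.default_rng(tree_seed)
    stage2 = list(range(1, 1 + config.n_stage2))
    stage3 = list(range(1 + config.n_stage2, 1 + config.n_stage2 + config.n_stage3))
    while True:
        labels = [config.terminal_labels[i] for i in rng.permutation(config.n_stage3)]
        successors: dict[tuple[int, int], tuple[int, int]] = {}
        for a in ACTIONS:
            pair = rng.choice(stage2, size=2, replace=False)
            successors[(0, a)] = (int(pair[0]), int(pair[1]))
        for s in stage2:
            for a in ACTIONS:
                pair = rng.choice(stage3, size=2, replace=False)
                successors[(s, a)] = (int(pair[0]), int(pair[1]))
        tree = DecisionTree(
            n_stage2=config.n_stage2,
            n_stage3=config.n_stage3,
            successors=successors,
            terminal_value={t: COLOR_VALUE[c] for t, c in zip(stage3, labels)},
            terminal_color=dict(zip(stage3, labels)),
            tree_seed=tree_seed,
        )
        if set(GOAL_COLORS) <= tree.reachable_colors():
            tree.validate()
            return tree


def sample_transition(
    tree: DecisionTree,
    state: int,
    action: int,
    uncertainty: str,
    rng: np.random.Generator,
) -> int:
    """Sample the next state: likely successor w.p. 0.9 (low) or 0.5 (high)."""
    if tree.is_terminal(state):
        raise ValueError(f"state {state} is terminal")
    likely, unlikely = tree.successors[(state, action)]
    p = LIKELY_P[uncertainty]
    return likely if rng.random() < p else unlikely


def payout(tree: DecisionTree, s3: int, condition: str, goal_color: str | None) -> int:
    """Coins credited under the goal rule."""
    coins = tree.terminal_value[s3]
    if condition == "flexible":
        return coins
    return coins if tree.terminal_color[s3] == goal_color else 0


def optimal_policy_value(
    tree: DecisionTree,
    condition: str,
    goal_color: str | None,
    uncertainty: str,
) -> tuple[dict[tuple[int, int], float], dict[int, tuple[int, ...]]]:
    """Backward induction on the TRUE transition probabilities.

    Returns ``(q, optimal)`` where ``q[(state, action)]`` is the expected
    reward of taking ``action`` in ``state`` and acting optimally after,
    and ``optimal[state]`` is the tuple of reward-maximizing actions
    (both actions on a tie)."""
    p = LIKELY_P[uncertainty]
    probs = (p, 1.0 - p)
    r = {t: float(payout(tree, t, condition, goal_color)) for t in tree.stage3_states}
    q: dict[tuple[int, int], float] = {}
    v: dict[int, float] = dict(r)
    for s in tree.stage2_states:
        for a in ACTIONS:
            q[(s, a)] = sum(
                pr * v[nxt] for pr, nxt in zip(probs, tree.successors[(s, a)])
            )
        v[s] = max(q[(s, 0)], q[(s, 1)])
    for a in ACTIONS:
        q[(0, a)] = sum(pr * v[nxt] for pr, nxt in zip(probs, tree.successors[(0, a)]))
    optimal: dict[int, tuple[int, ...]] = {}
    for s in tree.nonterminal_states():
        best = max(q[(s, 0)], q[(s, 1)])
        optimal[s] = tuple(a for a in ACTIONS if q[(s, a)] >= best - 1e-9)
    return q, optimal


# --------------------------------------------------------------------------
# Session schedules and trial records
# --------------------------------------------------------------------------

BLOCK_TYPES = tuple(itertools.product(CONDITIONS, UNCERTAINTIES))
N_BLOCKS_PER_TYPE = 14
TRIAL_RANGE = {"low": (3, 5), "high": (5, 7)}
N_TRAINING_FLEXIBLE = 80
N_TRAINING_SPECIFIC = 20


@dataclass(frozen=True)
class Block:
    condition: str
    uncertainty: str
    goal_color: str | None
    n_trials: int

    def __post_init__(self) -> None:
        if self.condition == "specific" and self.goal_color not in GOAL_COLORS:
            raise ValueError("specific blocks need a goal color")
        if self.condition == "flexible" and self.goal_color is not None:
            raise ValueError("flexible blocks carry no goal color")


@dataclass(frozen=True)
class SessionSchedule:
    blocks: tuple[Block, ...]
    schedule_seed: int
    phase: str = "main"

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "schedule_seed": self.schedule_seed,
            "phase": self.phase,
            "blocks": [
                {
                    "condition": b.condition,
                    "uncertainty": b.uncertainty,
                    "goal_color": b.goal_color,
                    "n_trials": b.n_trials,
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionSchedule":
        return cls(
            blocks=tuple(
                Block(b["condition"], b["uncertainty"], b["goal_color"], int(b["n_trials"]))
                for b in d["blocks"]
            ),
            schedule_seed=int(d["schedule_seed"]),
            phase=d.get("phase", "main"),
        )


def generate_schedule(schedule_seed: int) -> SessionSchedule:
    """Main-phase schedule: 14 blocks of each (condition, uncertainty)
    type in uniformly random order; block lengths drawn uniformly from
    3-5 trials (low uncertainty) or 5-7 trials (high)."""
    rng = np.random.default_rng(schedule_seed)
    blocks = []
    for condition, uncertainty in BLOCK_TYPES:
        lo, hi = TRIAL_RANGE[uncertainty]
        for _ in range(N_BLOCKS_PER_TYPE):
            goal = str(rng.choice(GOAL_COLORS)) if condition == "specific" else None
            n = int(rng.integers(lo, hi + 1))
            blocks.append(Block(condition, uncertainty, goal, n))
    order = rng.permutation(len(blocks))
    return SessionSchedule(tuple(blocks[i] for i in order), schedule_seed, "main")


def generate_training_schedule(schedule_seed: int) -> SessionSchedule:
    """Training phase: 80 flexible trials followed by 20 specific trials
    (goal color redrawn every trial).  Modeled as 100 one-trial blocks
    with per-trial uniform uncertainty; excluded from fitting/metrics."""
    rng = np.random.default_rng(schedule_seed)
    blocks = []
    for _ in range(N_TRAINING_FLEXIBLE):
        blocks.append(Block("flexible", str(rng.choice(UNCERTAINTIES)), None, 1))
    for _ in range(N_TRAINING_SPECIFIC):
        blocks.append(
            Block("specific", str(rng.choice(UNCERTAINTIES)), str(rng.choice(GOAL_COLORS)), 1)
        )
    return SessionSchedule(tuple(blocks), schedule_seed, "training")


@dataclass
class TrialRecord:
    """One trial of a session log.  ``missing`` trials (timeouts) carry
    no states/actions; their integer fields are set to -1."""

    trial_index: int
    block_index: int
    condition: str
    uncertainty: str
    goal_color: str | None
    s1: int
    a1: int
    s2: int
    a2: int
    s3: int
    coins_shown: int
    reward_paid: int
    missing: bool = False
    subject_id: str = ""

    def validate(self, tree: DecisionTree) -> None:
        if self.missing:
            return
        if self.s2 not in tree.successors[(self.s1, self.a1)]:
            raise ValueError(
                f"trial {self.trial_index}: s2={self.s2} is not a successor of "
                f"(s1={self.s1}, a1={self.a1})"
            )
        if self.s3 not in tree.successors[(self.s2, self.a2)]:
            raise ValueError(
                f"trial {self.trial_index}: s3={self.s3} is not a successor of "
                f"(s2={self.s2}, a2={self.a2})"
            )
        if self.coins_shown != tree.terminal_value[self.s3]:
            raise ValueError(f"trial {self.trial_index}: coins_shown mismatch")
        expect = payout(tree, self.s3, self.condition, self.goal_color)
        if self.reward_paid != expect:
            raise ValueError(f"trial {self.trial_index}: reward_paid violates goal rule")


def validate_session(trials: list[TrialRecord], tree: DecisionTree) -> None:
    for t in trials:
        t.validate(tree)
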