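"""Synthetic agents: generative use of the MF/MB learners to simulate
full sessions with known ground-truth parameters and mixing weights.

The mixture weight ``w`` is the probability that a given trial's two
decisions are driven by the MB policy (one system controls a whole trial
by default, matching the per-trial preference measure); decision-level
mixing is available via ``decision_level=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .learners import MBState, MFState, backward_plan, mb_spe_update, mf_update, softmax_prob
from .task import (
    DecisionTree,
    SessionSchedule,
    TopologyConfig,
    TrialRecord,
    generate_schedule,
    generate_tree,
    payout,
    sample_transition,
)

AGENT_KINDS = ("random", "pure_mf", "pure_mb", "mixture")


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth description of one simulated subject."""

    kind: str = "mixture"
    mf_params: tuple[float, float] = (0.3, 0.15)  # (alpha, tau_MF)
    mb_params: tuple[float, float] = (0.3, 0.15)  # (eta, tau_MB)
    mixture_weight: float = 0.5
    condition_dependent_w: tuple[float, float] | None = None  # (w_specific, w_flexible)
    lapse_rate: float = 0.0
    missing_rate: float = 0.0
    decision_level: bool = False
    agent_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.kind == "pure_mf":
            object.__setattr__(self, "mixture_weight", 0.0)
            object.__setattr__(self, "condition_dependent_w", None)
        elif self.kind == "pure_mb":
            object.__setattr__(self, "mixture_weight", 1.0)
            object.__setattr__(self, "condition_dependent_w", None)
        for name in ("mixture_weight", "lapse_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.condition_dependent_w is not None:
            for v in self.condition_dependent_w:
                if not 0.0 <= v <= 1.0:
                    raise ValueError("condition-dependent weights must be in [0, 1]")

    def weight_for(self, condition: str) -> float:
        if self.condition_dependent_w is None:
            return self.mixture_weight
        return self.condition_dependent_w[0 if condition == "specific" else 1]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mf_alpha": self.mf_params[0],
            "mf_tau": self.mf_params[1],
            "mb_eta": self.mb_params[0],
            "mb_tau": self.mb_params[1],
            "mixture_weight": self.mixture_weight,
            "w_specific": None if self.condition_dependent_w is None
            else self.condition_dependent_w[0],
            "w_flexible": None if self.condition_dependent_w is None
            else self.condition_dependent_w[1],
            "lapse_rate": self.lapse_rate,
            "missing_rate": self.missing_rate,
            "agent_seed": self.agent_seed,
        }


def _choose(rng: np.random.Generator, probs: np.ndarray) -> int:
    return 0 if rng.random() < probs[0] else 1


def simulate_session(
    tree: DecisionTree,
    schedule: SessionSchedule,
    agent: AgentSpec,
    subject_id: str = "",
) -> list[TrialRecord]:
    """Run both learners forward through a schedule, with the controlling
    system drawn per trial from the (condition-dependent) mixture weight.
    Both learners update from every experienced outcome; fully reproducible
    from the agent seed."""
    rng = np.random.default_rng(agent.agent_seed)
    mf = MFState.init(tree, *agent.mf_params)
    mb = MBState.init(tree, *agent.mb_params)
    trials: list[TrialRecord] = []
    idx = 0
    for bi, block in enumerate(schedule.blocks):
        for _ in range(block.n_trials):
            if rng.random() < agent.missing_rate:
                trials.append(TrialRecord(
                    trial_index=idx, block_index=bi, condition=block.condition,
                    uncertainty=block.uncertainty, goal_color=block.goal_color,
                    s1=-1, a1=-1, s2=-1, a2=-1, s3=-1,
                    coins_shown=0, reward_paid=0, missing=True,
                    subject_id=subject_id,
                ))
                idx += 1
                continue
            backward_plan(mb, tree, block.condition, block.goal_color)
            w = agent.weight_for(block.condition)
            use_mb = rng.random() < w

            def pick(state: int) -> int:
                nonlocal use_mb
                if agent.decision_level and state != tree.root:
                    use_mb = rng.random() < w
                if agent.kind == "random" or rng.random() < agent.lapse_rate:
                    return int(rng.integers(2))
                sys_state = mb if use_mb else mf
                return _choose(rng, softmax_prob(sys_state.q[state], sys_state.tau))

            s1 = tree.root
            a1 = pick(s1)
            s2 = sample_transition(tree, s1, a1, block.uncertainty, rng)
            a2 = pick(s2)
            s3 = sample_transition(tree, s2, a2, block.uncertainty, rng)
            coins = tree.terminal_value[s3]
            reward = payout(tree, s3, block.condition, block.goal_color)
            mf_update(mf, s1, a1, s2, a2, 0.0)
            mf_update(mf, s2, a2, s3, None, float(reward))
            mb_spe_update(mb, tree, s1, a1, s2)
            mb_spe_update(mb, tree, s2, a2, s3)
            trials.append(TrialRecord(
                trial_index=idx, block_index=bi, condition=block.condition,
                uncertainty=block.uncertainty, goal_color=block.goal_color,
                s1=s1, a1=a1, s2=s2, a2=a2, s3=s3,
                coins_shown=coins, reward_paid=reward, missing=False,
                subject_id=subject_id,
            ))
            idx += 1
    return trials


@dataclass
class SubjectData:
    subject_id: str
    group: str
    agent: AgentSpec
    tree: DecisionTree
    schedule: SessionSchedule
    trials: list[TrialRecord]


def make_cohort(
    n_per_group: int,
    group_specs: dict[str, dict],
    master_seed: int = 0,
    topology: TopologyConfig | None = None,
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate ``n_per_group`` subjects per group, each with an individual
    tree and schedule; returns the sessions plus a ground-truth table of
    the generating agent parameters."""
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    ss = np.random.SeedSequence(master_seed)
    subjects: list[SubjectData] = []
    rows = []
    for group, spec_kwargs in group_specs.items():
        for i in range(n_per_group):
            tree_seed, sched_seed, agent_seed = (
                int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
            )
            subject_id = f"{group}_{i:03d}"
            agent = AgentSpec(**{**spec_kwargs, "agent_seed": agent_seed})
            tree = generate_tree(tree_seed, topology)
            schedule = generate_schedule(sched_seed)
            trials = simulate_session(tree, schedule, agent, subject_id=subject_id)
            subjects.append(SubjectData(subject_id, group, agent, tree, schedule, trials))
            rows.append({"subject_id": subject_id, "group": group,
                         "tree_seed": tree_seed, "schedule_seed": sched_seed,
                         **agent.to_dict()})
    return subjects, pd.DataFrame(rows)
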