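"""Model-free SARSA and model-based transition-learning value computation.

The model-free (MF) learner caches action values ``Q_MF(s, a)`` updated by
reward prediction errors with discount fixed at 1.  The model-based (MB)
learner maintains a transition matrix ``T(s, a, s')`` updated by state
prediction errors, and derives ``Q_MB`` by planning backward through the
tree under the current goal rule.  Both select actions via a softmax with
inverse temperature ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import ACTIONS, DecisionTree, payout


def softmax_prob(q_values: np.ndarray, tau: float) -> np.ndarray:
    """P(a) = exp(tau*Q(a)) / sum_b exp(tau*Q(b)), overflow-safe."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    z = tau * np.asarray(q_values, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class MFState:
    """SARSA action values.  ``q`` has shape (n_states, 2), zero-initialized;
    the discount factor is fixed at 1 and is not a free parameter."""

    q: np.ndarray
    alpha: float
    tau: float
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    @classmethod
    def init(cls, tree: DecisionTree, alpha: float, tau: float) -> "MFState":
        return cls(q=np.zeros((tree.n_states, 2)), alpha=alpha, tau=tau)

    def action_probs(self, state: int) -> np.ndarray:
        return softmax_prob(self.q[state], self.tau)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "tau": self.tau, "gamma": self.gamma,
                "q": self.q.tolist()}


def mf_update(
    mf: MFState,
    s: int,
    a: int,
    s_next: int,
    a_next: int | None,
    reward: float,
) -> MFState:
    """One SARSA step: delta = r + gamma*Q(s', a') - Q(s, a);
    Q(s, a) += alpha * delta.  Terminal s' bootstraps with 0 (a_next None).
    Updates in place and returns the state."""
    bootstrap = 0.0 if a_next is None else mf.q[s_next, a_next]
    delta = reward + mf.gamma * bootstrap - mf.q[s, a]
    mf.q[s, a] += mf.alpha * delta
    return mf


@dataclass
class MBState:
    """Transition model and planned values.

    ``t[s, a, j]`` is the probability of the j-th candidate successor of
    (s, a); rows live on the 2-simplex restricted to the tree's candidate
    successors and start uniform.  ``q`` holds the values from the most
    recent backward plan.
    """

    t: np.ndarray
    q: np.ndarray
    eta: float
    tau: float
    current_goal: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    @classmethod
    def init(cls, tree: DecisionTree, eta: float, tau: float) -> "MBState":
        n_nonterminal = 1 + tree.n_stage2
        return cls(
            t=np.full((n_nonterminal, 2, 2), 0.5),
            q=np.zeros((n_nonterminal, 2)),
            eta=eta,
            tau=tau,
        )

    def action_probs(self, state: int) -> np.ndarray:
        return softmax_prob(self.q[state], self.tau)

    def to_dict(self) -> dict:
        return {"eta": self.eta, "tau": self.tau, "current_goal": self.current_goal,
                "t": self.t.tolist(), "q": self.q.tolist()}


def mb_spe_update(mb: MBState, tree: DecisionTree, s: int, a: int, s_next: int) -> MBState:
    """State-prediction-error update of the transition row for (s, a).

    delta_SPE = 1 - T(s, a, s'); the observed successor gains
    eta * delta_SPE while the other candidate is rescaled by (1 - eta),
    keeping the row on the simplex.  Updates in place.
    """
    candidates = tree.successors[(s, a)]
    if s_next not in candidates:
        raise ValueError(f"{s_next} is not a candidate successor of ({s}, {a})")
    j = candidates.index(s_next)
    row = mb.t[s, a]
    row *= 1.0 - mb.eta
    row[j] += mb.eta
    return mb


def backward_plan(
    mb: MBState,
    tree: DecisionTree,
    condition: str,
    goal_color: str | None,
) -> MBState:
    """Recompute Q_MB by backward induction over the learned T.

    Terminal rewards follow the goal rule (flexible: every coin value;
    specific: goal-colored coins only), then for stages 3, 2 backward:
    Q_MB(s, a) = sum_s' T(s, a, s') * (r(s') + max_a' Q_MB(s', a')),
    with the max defined as 0 at terminals.
    """
    r = {t: float(payout(tree, t, condition, goal_color)) for t in tree.stage3_states}
    for s in tree.stage2_states:
        for a in ACTIONS:
            mb.q[s, a] = sum(
                mb.t[s, a, j] * r[nxt]
                for j, nxt in enumerate(tree.successors[(s, a)])
            )
    for a in ACTIONS:
        mb.q[0, a] = sum(
            mb.t[0, a, j] * max(mb.q[nxt, 0], mb.q[nxt, 1])
            for j, nxt in enumerate(tree.successors[(0, a)])
        )
    mb.current_goal = goal_color if condition == "specific" else "flexible"
    return mb
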