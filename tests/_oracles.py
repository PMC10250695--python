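"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own recursions: expected rewards are
computed by exhaustive path enumeration over state-contingent policies,
planning is checked by generic value iteration, and session likelihoods are
re-derived step by step through the readable learner API.
"""

import itertools
import math

import numpy as np

from arbitrl.learners import MBState, MFState, backward_plan, mb_spe_update, mf_update
from arbitrl.task import ACTIONS, LIKELY_P, payout


def policy_value(tree, condition, goal_color, uncertainty, a1, a2_map):
    """Expected reward of (root action a1, per-stage-2-state action map) by
    exhaustive path enumeration."""
    p = LIKELY_P[uncertainty]
    probs = (p, 1.0 - p)
    total = 0.0
    for p2, s2 in zip(probs, tree.successors[(0, a1)]):
        a2 = a2_map[s2]
        for p3, s3 in zip(probs, tree.successors[(s2, a2)]):
            total += p2 * p3 * payout(tree, s3, condition, goal_color)
    return total


def best_contingent_value(tree, condition, goal_color, uncertainty):
    """Max expected reward over all state-contingent policies."""
    s2_states = list(tree.stage2_states)
    best = -math.inf
    for a1 in ACTIONS:
        for assignment in itertools.product(ACTIONS, repeat=len(s2_states)):
            a2_map = dict(zip(s2_states, assignment))
            best = max(best, policy_value(tree, condition, goal_color, uncertainty, a1, a2_map))
    return best


def best_fixed_sequence_value(tree, condition, goal_color, uncertainty):
    """Max expected reward over the 4 fixed (a1, a2) sequences."""
    s2_states = list(tree.stage2_states)
    return max(
        policy_value(tree, condition, goal_color, uncertainty, a1,
                     {s: a2 for s in s2_states})
        for a1 in ACTIONS for a2 in ACTIONS
    )


def value_iteration(tree, t_rows, terminal_reward, tol=1e-12, max_iter=10_000):
    """Generic value iteration on transition rows ``t_rows[(s, a)]``
    (probabilities over the tree's candidate successors) and terminal
    rewards; returns Q over non-terminal (state, action)."""
    v = {s: 0.0 for s in range(tree.n_states)}
    q = {}
    for _ in range(max_iter):
        delta = 0.0
        for s in tree.nonterminal_states():
            for a in ACTIONS:
                q[(s, a)] = sum(
                    pr * (terminal_reward.get(nxt, 0.0) + v[nxt])
                    for pr, nxt in zip(t_rows[(s, a)], tree.successors[(s, a)])
                )
            new_v = max(q[(s, 0)], q[(s, 1)])
            delta = max(delta, abs(new_v - v[s]))
            v[s] = new_v
        if delta < tol:
            break
    return q


def reference_replay(trials, tree, learner_kind, params, p_floor=1e-12):
    """Step-by-step session replay via the public learner API; returns
    (nll, per-decision probabilities (n, 2) with NaN for missing)."""
    rate, tau = params
    mf = MFState.init(tree, rate, tau)
    mb = MBState.init(tree, rate, tau)
    n = len(trials)
    probs = np.full((n, 2), np.nan)
    nll = 0.0
    for i, tr in enumerate(trials):
        if tr.missing:
            continue
        if learner_kind == "MB":
            backward_plan(mb, tree, tr.condition, tr.goal_color)
            q = mb.q
        else:
            q = mf.q
        for j, (s, a) in enumerate(((tr.s1, tr.a1), (tr.s2, tr.a2))):
            z = tau * q[s]
            e = np.exp(z - z.max())
            p = max(float(e[a] / e.sum()), p_floor)
            probs[i, j] = p
            nll -= math.log(p)
        mf_update(mf, tr.s1, tr.a1, tr.s2, tr.a2, 0.0)
        mf_update(mf, tr.s2, tr.a2, tr.s3, None, float(tr.reward_paid))
        mb_spe_update(mb, tree, tr.s1, tr.a1, tr.s2)
        mb_spe_update(mb, tree, tr.s2, tr.a2, tr.s3)
    return nll, probs
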