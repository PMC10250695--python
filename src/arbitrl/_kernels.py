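"""Hot-path session replay kernels.

The likelihood of a session is evaluated tens of thousands of times during
multi-restart Nelder-Mead fitting, so the replay loops are JIT-compiled
with numba when available and fall back to plain Python otherwise.  The
public, readable implementations live in :mod:`arbitrl.learners`; tests
assert the two paths agree to 1e-9.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is normally installed
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

_P_FLOOR = 1e-12


@njit(cache=False)
def _pair_softmax(q0: float, q1: float, tau: float, chosen: int) -> float:
    m = q0 if q0 > q1 else q1
    e0 = math.exp(tau * (q0 - m))
    e1 = math.exp(tau * (q1 - m))
    p = (e0 if chosen == 0 else e1) / (e0 + e1)
    if p < _P_FLOOR:
        p = _P_FLOOR
    return p


@njit(cache=False)
def mf_replay(
    alpha: float,
    tau: float,
    s1: np.ndarray,
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    reward: np.ndarray,
    missing: np.ndarray,
    n_states: int,
) -> np.ndarray:
    """SARSA replay; returns per-decision choice probabilities
    (n_trials, 2), NaN for missing trials."""
    n = s1.shape[0]
    q = np.zeros((n_states, 2))
    probs = np.full((n, 2), np.nan)
    for i in range(n):
        if missing[i]:
            continue
        probs[i, 0] = _pair_softmax(q[s1[i], 0], q[s1[i], 1], tau, a1[i])
        probs[i, 1] = _pair_softmax(q[s2[i], 0], q[s2[i], 1], tau, a2[i])
        # first transition pays 0, bootstraps on Q(s2, a2)
        d1 = q[s2[i], a2[i]] - q[s1[i], a1[i]]
        q[s1[i], a1[i]] += alpha * d1
        # terminal transition pays reward, bootstraps 0
        d2 = reward[i] - q[s2[i], a2[i]]
        q[s2[i], a2[i]] += alpha * d2
    return probs


@njit(cache=False)
def mb_replay(
    eta: float,
    tau: float,
    s1: np.ndarray,
    a1: np.ndarray,
    s2: np.ndarray,
    a2: np.ndarray,
    j1: np.ndarray,
    j2: np.ndarray,
    missing: np.ndarray,
    succ: np.ndarray,
    r_term: np.ndarray,
    n_nonterminal: int,
) -> np.ndarray:
    """Transition-learning replay with per-trial backward planning.

    ``succ[s, a, j]`` are candidate successor state ids for the
    non-terminal states ``0..n_nonterminal-1``; ``r_term[i, s]`` is the
    goal-gated terminal reward on trial ``i``; ``j1``/``j2`` index the
    observed successor within the candidate pair.
    """
    n = s1.shape[0]
    t = np.full((n_nonterminal, 2, 2), 0.5)
    q = np.zeros((n_nonterminal, 2))
    probs = np.full((n, 2), np.nan)
    for i in range(n):
        if missing[i]:
            continue
        # backward plan under this trial's goal
        for s in range(1, n_nonterminal):
            for a in range(2):
                q[s, a] = (
                    t[s, a, 0] * r_term[i, succ[s, a, 0]]
                    + t[s, a, 1] * r_term[i, succ[s, a, 1]]
                )
        for a in range(2):
            acc = 0.0
            for j in range(2):
                nxt = succ[0, a, j]
                v = q[nxt, 0] if q[nxt, 0] > q[nxt, 1] else q[nxt, 1]
                acc += t[0, a, j] * v
            q[0, a] = acc
        probs[i, 0] = _pair_softmax(q[0, 0], q[0, 1], tau, a1[i])
        probs[i, 1] = _pair_softmax(q[s2[i], 0], q[s2[i], 1], tau, a2[i])
        # SPE updates for both observed transitions
        t[s1[i], a1[i], 0] *= 1.0 - eta
        t[s1[i], a1[i], 1] *= 1.0 - eta
        t[s1[i], a1[i], j1[i]] += eta
        t[s2[i], a2[i], 0] *= 1.0 - eta
        t[s2[i], a2[i], 1] *= 1.0 - eta
        t[s2[i], a2[i], j2[i]] += eta
    return probs
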