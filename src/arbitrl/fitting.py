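"""Per-subject maximum-likelihood estimation of learner parameters.

A session is replayed decision by decision: the softmax probability of the
*chosen* action is recorded under the learner's current values, then the
learner is updated with the *observed* transition and reward.  The negative
log-likelihood over all non-missing decisions is minimized by Nelder-Mead
from many random starting points in an unconstrained reparameterization
(logit learning rate, log inverse temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _kernels
from .task import CONDITIONS, DecisionTree, TrialRecord, payout

LEARNER_KINDS = ("MF", "MB")

#: random-restart seed-parameter ranges
RATE_RANGE = (0.01, 0.99)
TAU_RANGE = (0.01, 10.0)

DEFAULT_N_RESTARTS = 200
_XATOL = 1e-6
_FATOL = 1e-6
_MAXFEV = 2000
_P_FLOOR = 1e-12


@dataclass(frozen=True)
class SessionArrays:
    """Session log flattened to ndarrays for the replay kernels; built
    once per (session, tree) and reused across likelihood evaluations."""

    s1: np.ndarray
    a1: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    j1: np.ndarray
    j2: np.ndarray
    reward: np.ndarray
    missing: np.ndarray
    condition: np.ndarray  # object array of condition strings
    succ: np.ndarray
    r_term: np.ndarray
    n_states: int
    n_nonterminal: int

    @property
    def n_trials(self) -> int:
        return self.s1.shape[0]

    @property
    def n_decisions(self) -> int:
        return 2 * int((~self.missing).sum())


def build_session_arrays(trials: list[TrialRecord], tree: DecisionTree) -> SessionArrays:
    """Validate a session against its tree and pack it into arrays."""
    n = len(trials)
    n_nonterminal = 1 + tree.n_stage2
    s1 = np.zeros(n, dtype=np.int64)
    a1 = np.zeros(n, dtype=np.int64)
    s2 = np.zeros(n, dtype=np.int64)
    a2 = np.zeros(n, dtype=np.int64)
    j1 = np.zeros(n, dtype=np.int64)
    j2 = np.zeros(n, dtype=np.int64)
    reward = np.zeros(n, dtype=np.float64)
    missing = np.zeros(n, dtype=np.bool_)
    condition = np.empty(n, dtype=object)
    r_term = np.zeros((n, tree.n_states), dtype=np.float64)
    for i, tr in enumerate(trials):
        tr.validate(tree)
        condition[i] = tr.condition
        if tr.missing:
            missing[i] = True
            continue
        s1[i], a1[i], s2[i], a2[i] = tr.s1, tr.a1, tr.s2, tr.a2
        j1[i] = tree.successors[(tr.s1, tr.a1)].index(tr.s2)
        j2[i] = tree.successors[(tr.s2, tr.a2)].index(tr.s3)
        reward[i] = tr.reward_paid
        for t in tree.stage3_states:
            r_term[i, t] = payout(tree, t, tr.condition, tr.goal_color)
    succ = np.zeros((n_nonterminal, 2, 2), dtype=np.int64)
    for s in tree.nonterminal_states():
        for a in (0, 1):
            succ[s, a] = tree.successors[(s, a)]
    return SessionArrays(
        s1=s1, a1=a1, s2=s2, a2=a2, j1=j1, j2=j2, reward=reward,
        missing=missing, condition=condition, succ=succ, r_term=r_term,
        n_states=tree.n_states, n_nonterminal=n_nonterminal,
    )


def _decision_probs(arrays: SessionArrays, learner_kind: str, params) -> np.ndarray:
    rate, tau = float(params[0]), float(params[1])
    if not 0.0 < rate < 1.0:
        raise ValueError(f"learning rate must be in (0, 1), got {rate}")
    if tau < 0.0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    if learner_kind == "MF":
        return _kernels.mf_replay(
            rate, tau, arrays.s1, arrays.a1, arrays.s2, arrays.a2,
            arrays.reward, arrays.missing, arrays.n_states,
        )
    if learner_kind == "MB":
        return _kernels.mb_replay(
            rate, tau, arrays.s1, arrays.a1, arrays.s2, arrays.a2,
            arrays.j1, arrays.j2, arrays.missing, arrays.succ,
            arrays.r_term, arrays.n_nonterminal,
        )
    raise ValueError(f"unknown learner kind {learner_kind!r}")


def session_nll(
    session: list[TrialRecord] | SessionArrays,
    tree: DecisionTree | None = None,
    learner_kind: str = "MF",
    params: tuple[float, float] = (0.5, 1.0),
    per_decision: bool = False,
) -> tuple[float, np.ndarray]:
    """Replay a session under one learner and return
    ``(nll, per_trial_likelihood)``.

    ``params`` is ``(learning_rate, tau)``.  Missing trials contribute
    nothing to the NLL and do not update the learner; their likelihood
    entries are NaN.  With ``per_decision=True`` the raw (n_trials, 2)
    decision probabilities are returned instead of per-trial products.
    """
    if isinstance(session, SessionArrays):
        arrays = session
    else:
        if tree is None:
            raise ValueError("tree is required when passing raw trials")
        arrays = build_session_arrays(session, tree)
    probs = _decision_probs(arrays, learner_kind, params)
    ok = ~arrays.missing
    nll = float(-np.log(probs[ok]).sum())
    trace = probs if per_decision else probs[:, 0] * probs[:, 1]
    return nll, trace


@dataclass
class FitResult:
    """Best-of-restarts maximum-likelihood fit for one learner."""

    learner_kind: str
    params: tuple[float, float]  # (learning_rate, tau)
    nll: float
    n_restarts: int
    restart_nlls: list[float]
    per_trial_likelihood: np.ndarray
    converged: bool

    @property
    def learning_rate(self) -> float:
        return self.params[0]

    @property
    def tau(self) -> float:
        return self.params[1]

    def to_dict(self) -> dict:
        return {
            "learner_kind": self.learner_kind,
            "params": {"learning_rate": self.params[0], "tau": self.params[1]},
            "nll": self.nll,
            "n_restarts": self.n_restarts,
            "restart_nlls": list(self.restart_nlls),
            "per_trial_likelihood": [
                None if np.isnan(x) else float(x) for x in self.per_trial_likelihood
            ],
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            learner_kind=d["learner_kind"],
            params=(d["params"]["learning_rate"], d["params"]["tau"]),
            nll=float(d["nll"]),
            n_restarts=int(d["n_restarts"]),
            restart_nlls=[float(x) for x in d["restart_nlls"]],
            per_trial_likelihood=np.array(
                [np.nan if x is None else x for x in d["per_trial_likelihood"]],
                dtype=float,
            ),
            converged=bool(d["converged"]),
        )


def _to_unconstrained(rate: float, tau: float) -> np.ndarray:
    return np.array([logit(rate), np.log(tau)])


def _from_unconstrained(x: np.ndarray) -> tuple[float, float]:
    rate = float(np.clip(expit(x[0]), 1e-9, 1 - 1e-9))
    tau = float(np.exp(np.clip(x[1], -50.0, 50.0)))
    return rate, tau


def fit_learner(
    session: list[TrialRecord] | SessionArrays,
    tree: DecisionTree | None = None,
    learner_kind: str = "MF",
    n_restarts: int = DEFAULT_N_RESTARTS,
    rng: np.random.Generator | int | None = None,
) -> FitResult:
    """Minimize the session NLL over (learning_rate, tau) by Nelder-Mead
    from ``n_restarts`` random seed parameters; deterministic given the rng
    seed.  Returns the best restart even if none formally converged."""
    if isinstance(session, SessionArrays):
        arrays = session
    else:
        if tree is None:
            raise ValueError("tree is required when passing raw trials")
        arrays = build_session_arrays(session, tree)
    if arrays.n_decisions == 0:
        raise ValueError("session has no non-missing trials to fit")
    rng = np.random.default_rng(rng)
    ok = ~arrays.missing

    def objective(x: np.ndarray) -> float:
        rate, tau = _from_unconstrained(x)
        probs = _decision_probs(arrays, learner_kind, (rate, tau))
        return float(-np.log(probs[ok]).sum())

    best = None
    restart_nlls: list[float] = []
    any_converged = False
    for _ in range(n_restarts):
        rate0 = rng.uniform(*RATE_RANGE)
        tau0 = float(np.exp(rng.uniform(np.log(TAU_RANGE[0]), np.log(TAU_RANGE[1]))))
        res = minimize(
            objective,
            _to_unconstrained(rate0, tau0),
            method="Nelder-Mead",
            options={"xatol": _XATOL, "fatol": _FATOL, "maxfev": _MAXFEV},
        )
        restart_nlls.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _from_unconstrained(best.x)
    nll, trace = session_nll(arrays, learner_kind=learner_kind, params=params)
    return FitResult(
        learner_kind=learner_kind,
        params=params,
        nll=nll,
        n_restarts=n_restarts,
        restart_nlls=restart_nlls,
        per_trial_likelihood=trace,
        converged=any_converged,
    )
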