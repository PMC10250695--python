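"""Per-subject dependent measures: system preference, switching,
arbitration, and raw task performance.

The "dominant system" on a trial is the learner (MF or MB) whose fitted
per-trial likelihood is higher; ties count as MF-dominant for the
preference measure and inherit the previous trial's dominance for the
switching measure.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .task import DecisionTree, TrialRecord, optimal_policy_value


def mb_preference(
    mf_trace: np.ndarray,
    mb_trace: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Percentage of non-missing masked trials on which the MB per-trial
    likelihood exceeds the MF one (ties count as non-MB)."""
    mf_trace = np.asarray(mf_trace, dtype=float)
    mb_trace = np.asarray(mb_trace, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mf_trace.shape != mb_trace.shape or mf_trace.shape != mask.shape:
        raise ValueError("traces and mask must have identical length")
    ok = mask & ~np.isnan(mf_trace) & ~np.isnan(mb_trace)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no non-missing trials in mask")
    return 100.0 * float((mb_trace[ok] > mf_trace[ok]).sum()) / n


def dominant_system(mf_trace: np.ndarray, mb_trace: np.ndarray) -> np.ndarray:
    """Per-trial dominant system: 'MB', 'MF', or 'tie' (NaN-safe: missing
    trials come out as 'missing')."""
    mf_trace = np.asarray(mf_trace, dtype=float)
    mb_trace = np.asarray(mb_trace, dtype=float)
    out = np.full(mf_trace.shape, "missing", dtype=object)
    ok = ~np.isnan(mf_trace) & ~np.isnan(mb_trace)
    out[ok & (mb_trace > mf_trace)] = "MB"
    out[ok & (mb_trace < mf_trace)] = "MF"
    out[ok & (mb_trace == mf_trace)] = "tie"
    return out


def switching_rate(dominant: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of consecutive within-condition trial pairs whose
    dominant system differs.

    The masked trials are concatenated in session order (block boundaries
    within a condition are not breaks); ties inherit the previous trial's
    dominance, and a leading tie counts as MF.
    """
    dominant = np.asarray(dominant, dtype=object)
    mask = np.asarray(mask, dtype=bool)
    seq = [d for d, m in zip(dominant, mask) if m and d != "missing"]
    if len(seq) < 2:
        raise ValueError("need at least 2 non-missing trials in mask")
    resolved = []
    prev = "MF"
    for d in seq:
        if d == "tie":
            d = prev
        resolved.append(d)
        prev = d
    switches = sum(1 for a, b in zip(resolved, resolved[1:]) if a != b)
    return 100.0 * switches / (len(resolved) - 1)


def arbitration_score(pref_specific: float, pref_flexible: float) -> float:
    """Ratio of MB preference in the specific vs flexible condition;
    NaN when the flexible preference is 0 (undefined)."""
    if pref_flexible == 0:
        return float("nan")
    return pref_specific / pref_flexible


def performance(
    trials: list[TrialRecord],
    tree: DecisionTree,
) -> dict[str, dict[str, float]]:
    """Mean coins earned and choice optimality, per condition.

    A trial is optimal when the first action is optimal at the root and
    the second action is optimal at the stage-2 state actually reached,
    under backward induction on the true transition probabilities (any
    tied action counts as optimal).
    """
    opt_cache: dict[tuple, dict] = {}
    acc: dict[str, dict[str, list]] = {
        "specific": {"coins": [], "optimal": []},
        "flexible": {"coins": [], "optimal": []},
    }
    for tr in trials:
        if tr.missing:
            continue
        key = (tr.condition, tr.goal_color, tr.uncertainty)
        if key not in opt_cache:
            _, opt_cache[key] = optimal_policy_value(tree, *key)
        optimal = opt_cache[key]
        acc[tr.condition]["coins"].append(tr.reward_paid)
        is_opt = tr.a1 in optimal[tr.s1] and tr.a2 in optimal[tr.s2]
        acc[tr.condition]["optimal"].append(is_opt)
    out = {}
    for cond, d in acc.items():
        n = len(d["coins"])
        out[cond] = {
            "mean_coins": float(np.mean(d["coins"])) if n else float("nan"),
            "choice_optimality": 100.0 * float(np.mean(d["optimal"])) if n else float("nan"),
        }
    return out


@dataclass
class StrategyMetrics:
    subject_id: str
    mb_preference_specific: float
    mb_preference_flexible: float
    switching_rate_specific: float
    switching_rate_flexible: float
    mean_coins_specific: float
    mean_coins_flexible: float
    choice_optimality_specific: float
    choice_optimality_flexible: float
    arbitration_score: float

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_strategy_metrics(
    trials: list[TrialRecord],
    tree: DecisionTree,
    mf_trace: np.ndarray,
    mb_trace: np.ndarray,
    subject_id: str = "",
) -> StrategyMetrics:
    """Assemble all per-subject measures from a session and the fitted
    per-trial likelihood traces of the two learners."""
    if len(mf_trace) != len(trials) or len(mb_trace) != len(trials):
        raise ValueError("likelihood traces must align with trials")
    cond = np.array([t.condition for t in trials], dtype=object)
    dom = dominant_system(mf_trace, mb_trace)
    prefs, switches = {}, {}
    for c in ("specific", "flexible"):
        mask = cond == c
        prefs[c] = mb_preference(mf_trace, mb_trace, mask)
        switches[c] = switching_rate(dom, mask)
    perf = performance(trials, tree)
    return StrategyMetrics(
        subject_id=subject_id,
        mb_preference_specific=prefs["specific"],
        mb_preference_flexible=prefs["flexible"],
        switching_rate_specific=switches["specific"],
        switching_rate_flexible=switches["flexible"],
        mean_coins_specific=perf["specific"]["mean_coins"],
        mean_coins_flexible=perf["flexible"]["mean_coins"],
        choice_optimality_specific=perf["specific"]["choice_optimality"],
        choice_optimality_flexible=perf["flexible"]["choice_optimality"],
        arbitration_score=arbitration_score(prefs["specific"], prefs["flexible"]),
    )


def metrics_table(metrics: list[StrategyMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in metrics])
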