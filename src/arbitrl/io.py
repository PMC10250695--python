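"""Readers/writers for session logs, trees, schedules, fits and metrics,
plus the end-to-end pipeline runner with its reproducibility manifest.

Formats: CSV for tabular trial/metrics data, JSON for trees/schedules/
fits/manifests, YAML for run configs.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import AgentSpec, SubjectData, make_cohort
from .fitting import FitResult, fit_learner
from .metrics import compute_strategy_metrics, metrics_table
from .stats import compare_groups, paired_and_correlational
from .task import (
    DecisionTree,
    SessionSchedule,
    TopologyConfig,
    TrialRecord,
    validate_session,
)

SESSION_COLUMNS = [
    "subject_id", "trial_index", "block_index", "condition", "uncertainty",
    "goal_color", "s1", "a1", "s2", "a2", "s3", "coins_shown", "reward_paid",
    "missing",
]


def session_to_dataframe(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "subject_id": t.subject_id,
            "trial_index": t.trial_index,
            "block_index": t.block_index,
            "condition": t.condition,
            "uncertainty": t.uncertainty,
            "goal_color": "" if t.goal_color is None else t.goal_color,
            "s1": t.s1, "a1": t.a1, "s2": t.s2, "a2": t.a2, "s3": t.s3,
            "coins_shown": t.coins_shown,
            "reward_paid": t.reward_paid,
            "missing": int(t.missing),
        })
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_csv(trials: list[TrialRecord], path: str | Path) -> None:
    session_to_dataframe(trials).to_csv(path, index=False)


def read_session_csv(path: str | Path, tree: DecisionTree | None = None) -> list[TrialRecord]:
    """Read a session log; if a tree is given, every row is validated
    against it and the offending row is named on failure."""
    df = pd.read_csv(path, keep_default_na=False, dtype={"goal_color": str})
    missing_cols = set(SESSION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    trials = []
    for _, row in df.iterrows():
        trials.append(TrialRecord(
            trial_index=int(row.trial_index),
            block_index=int(row.block_index),
            condition=str(row.condition),
            uncertainty=str(row.uncertainty),
            goal_color=None if row.goal_color == "" else str(row.goal_color),
            s1=int(row.s1), a1=int(row.a1), s2=int(row.s2), a2=int(row.a2),
            s3=int(row.s3),
            coins_shown=int(row.coins_shown),
            reward_paid=int(row.reward_paid),
            missing=bool(int(row.missing)),
            subject_id=str(row.subject_id),
        ))
    if tree is not None:
        for t in trials:
            try:
                t.validate(tree)
            except ValueError as e:
                raise ValueError(f"{path}: {e}") from e
    return trials


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_tree_json(tree: DecisionTree, path: str | Path) -> None:
    write_json(tree.to_dict(), path)


def read_tree_json(path: str | Path) -> DecisionTree:
    return DecisionTree.from_dict(read_json(path))


def write_schedule_json(schedule: SessionSchedule, path: str | Path) -> None:
    write_json(schedule.to_dict(), path)


def read_schedule_json(path: str | Path) -> SessionSchedule:
    return SessionSchedule.from_dict(read_json(path))


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    write_json(fit.to_dict(), path)


def read_fit_json(path: str | Path) -> FitResult:
    return FitResult.from_dict(read_json(path))


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully determines a pipeline run (every random process has an
    explicit seed)."""

    seed: int = 0
    n_per_group: int = 4
    groups: dict[str, dict] = field(default_factory=lambda: {
        "intact": {"kind": "mixture", "condition_dependent_w": (1.0, 0.0)},
        "impaired": {"kind": "mixture", "condition_dependent_w": (0.6, 0.4)},
    })
    topology: dict = field(default_factory=dict)
    n_restarts: int = 20
    fit_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.groups = {
            g: {**spec,
                **({"condition_dependent_w": tuple(spec["condition_dependent_w"])}
                   if spec.get("condition_dependent_w") is not None else {}),
                **({"mf_params": tuple(spec["mf_params"])} if "mf_params" in spec else {}),
                **({"mb_params": tuple(spec["mb_params"])} if "mb_params" in spec else {})}
            for g, spec in cfg.groups.items()
        }
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "groups": {g: {k: list(v) if isinstance(v, tuple) else v
                           for k, v in spec.items()}
                       for g, spec in self.groups.items()},
            "topology": self.topology,
            "n_restarts": self.n_restarts,
            "fit_seed": self.fit_seed,
            "log_level": self.log_level,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stable_hash(s: str) -> int:
    # process-independent (unlike builtin hash with PYTHONHASHSEED)
    return int(hashlib.sha256(s.encode()).hexdigest()[:8], 16)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """gen-task -> simulate -> fit -> metrics -> stats, writing all
    artifacts plus a manifest under ``outdir``.  Rerunning with the same
    config reproduces identical outputs."""
    outdir = Path(outdir)
    (outdir / "sessions").mkdir(parents=True, exist_ok=True)
    (outdir / "fits").mkdir(exist_ok=True)
    manifest: dict = {
        "tool": "arbitrl",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "files": {},
        "status": "incomplete",
    }
    manifest_path = outdir / "manifest.json"
    try:
        topology = TopologyConfig(**config.topology) if config.topology else None
        subjects, truth = make_cohort(
            config.n_per_group, config.groups, master_seed=config.seed,
            topology=topology,
        )
        truth.to_csv(outdir / "ground_truth.csv", index=False)
        all_metrics = []
        for subj in subjects:
            base = outdir / "sessions" / subj.subject_id
            write_session_csv(subj.trials, f"{base}_session.csv")
            write_tree_json(subj.tree, f"{base}_tree.json")
            write_schedule_json(subj.schedule, f"{base}_schedule.json")
            fits = {}
            for kind in ("MF", "MB"):
                fit = fit_learner(
                    subj.trials, subj.tree, learner_kind=kind,
                    n_restarts=config.n_restarts,
                    rng=np.random.default_rng([config.fit_seed, _stable_hash(subj.subject_id)]),
                )
                write_fit_json(fit, outdir / "fits" / f"{subj.subject_id}_{kind.lower()}.json")
                fits[kind] = fit
            m = compute_strategy_metrics(
                subj.trials, subj.tree,
                fits["MF"].per_trial_likelihood, fits["MB"].per_trial_likelihood,
                subject_id=subj.subject_id,
            )
            all_metrics.append(m)
        table = metrics_table(all_metrics)
        table = table.merge(truth[["subject_id", "group"]], on="subject_id")
        table.to_csv(outdir / "metrics.csv", index=False)
        stats_out = {}
        for measure in ("mb_preference_specific", "mb_preference_flexible",
                        "arbitration_score", "mean_coins_specific",
                        "mean_coins_flexible"):
            try:
                stats_out[measure] = compare_groups(table, measure).to_dict()
            except ValueError as e:
                stats_out[measure] = {"error": str(e)}
        try:
            stats_out["paired_and_correlational"] = paired_and_correlational(table)
        except ValueError as e:
            stats_out["paired_and_correlational"] = {"error": str(e)}
        write_json(stats_out, outdir / "stats.json")
        manifest["status"] = "complete"
    finally:
        for p in sorted(outdir.rglob("*")):
            if p.is_file() and p != manifest_path:
                manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
        write_json(manifest, manifest_path)
    return outdir
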