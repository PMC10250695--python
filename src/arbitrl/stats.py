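"""Group-level comparisons on a per-subject metrics table.

Thin wrappers around statsmodels/scipy: one-way ANOVA (or ANCOVA when
covariates are supplied) with pairwise post-hoc comparisons emitted both
uncorrected and Tukey-adjusted, plus paired t-tests and Pearson
correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class GroupComparison:
    measure: str
    groups: list[str]
    statistic: float  # omnibus F
    p_value: float
    df: tuple[float, float]
    posthoc: dict[tuple[str, str], dict[str, float]]
    covariates: list[str]
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "groups": self.groups,
            "F": self.statistic,
            "p": self.p_value,
            "df": list(self.df),
            "posthoc": {
                f"{a} vs {b}": v for (a, b), v in self.posthoc.items()
            },
            "covariates": self.covariates,
            "degenerate": self.degenerate,
        }


def _welch_anova(samples: list[np.ndarray]) -> tuple[float, float, tuple[float, float]]:
    # Welch (1951) heteroscedastic one-way F
    k = len(samples)
    n = np.array([len(s) for s in samples], dtype=float)
    m = np.array([s.mean() for s in samples])
    v = np.array([s.var(ddof=1) for s in samples])
    w = n / v
    mw = (w * m).sum() / w.sum()
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    tmp = ((1 - w / w.sum()) ** 2 / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * tmp
    f = num / den
    df2 = (k**2 - 1) / (3 * tmp)
    p = float(sps.f.sf(f, k - 1, df2))
    return float(f), p, (float(k - 1), float(df2))


def compare_groups(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    covariates: list[str] | None = None,
    welch: bool = False,
) -> GroupComparison:
    """Omnibus one-way ANOVA (classic by default, Welch on request) or
    linear-model ANCOVA when covariates are given, plus pairwise post-hoc
    comparisons (uncorrected and Tukey-style).  Two-sided throughout."""
    covariates = list(covariates or [])
    cols = [measure, group_col, *covariates]
    df = table[cols].dropna().copy()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (df[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    y = df[measure].to_numpy(dtype=float)
    degenerate = bool(np.ptp(y) == 0)
    if degenerate:
        return GroupComparison(measure, groups, float("nan"), float("nan"),
                               (float("nan"), float("nan")), {}, covariates, True)

    samples = [df.loc[df[group_col] == g, measure].to_numpy(dtype=float) for g in groups]
    if welch and not covariates:
        f, p, dfs = _welch_anova(samples)
    else:
        terms = " + ".join([f"C(Q('{group_col}'))"] + [f"Q('{c}')" for c in covariates])
        model = smf.ols(f"Q('{measure}') ~ {terms}", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        row = anova.loc[f"C(Q('{group_col}'))"]
        f = float(row["F"])
        p = float(row["PR(>F)"])
        dfs = (float(row["df"]), float(anova.loc["Residual", "df"]))

    posthoc: dict[tuple[str, str], dict[str, float]] = {}
    if covariates:
        # covariate-adjusted pairwise contrasts from the fitted model
        for a, b in itertools.combinations(groups, 2):
            sub = df[df[group_col].isin([a, b])]
            terms = " + ".join([f"C(Q('{group_col}'))"] + [f"Q('{c}')" for c in covariates])
            pm = smf.ols(f"Q('{measure}') ~ {terms}", data=sub).fit()
            coef = [c for c in pm.params.index if group_col in c][0]
            posthoc[(a, b)] = {
                "t": float(pm.tvalues[coef]),
                "p_uncorrected": float(pm.pvalues[coef]),
            }
    else:
        for (a, sa), (b, sb) in itertools.combinations(zip(groups, samples), 2):
            t, pu = sps.ttest_ind(sa, sb, equal_var=not welch)
            posthoc[(a, b)] = {"t": float(t), "p_uncorrected": float(pu)}
    # Tukey-style adjusted p-values on the raw measure
    tk = pairwise_tukeyhsd(y, df[group_col].to_numpy())
    for (a, b), p_adj in zip(
        itertools.combinations(groups, 2), tk.pvalues
    ):
        posthoc.setdefault((a, b), {})["p_tukey"] = float(p_adj)

    return GroupComparison(measure, groups, f, p, dfs, posthoc, covariates)


def paired_and_correlational(
    table: pd.DataFrame,
    group_col: str = "group",
    paired_cols: tuple[str, str] = ("mb_preference_specific", "mb_preference_flexible"),
    corr_pairs: tuple[tuple[str, str], ...] = (
        ("mb_preference_specific", "mean_coins_specific"),
        ("mb_preference_specific", "mean_coins_flexible"),
    ),
) -> dict[str, dict]:
    """Per group: paired t-test on the two preference columns and Pearson
    correlations between preference and performance columns."""
    out: dict[str, dict] = {}
    for g, sub in table.groupby(group_col):
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has n < 3")
        a = sub[paired_cols[0]].to_numpy(dtype=float)
        b = sub[paired_cols[1]].to_numpy(dtype=float)
        if np.allclose(a, b):
            t, p = 0.0, 1.0  # zero difference everywhere; scipy yields 0/0
        else:
            t, p = sps.ttest_rel(a, b)
        entry = {"paired_t": {"t": float(t), "p": float(p), "n": int(len(sub)),
                              "mean_diff": float(np.mean(a - b))}}
        for x, ycol in corr_pairs:
            r, rp = sps.pearsonr(sub[x], sub[ycol])
            entry[f"r({x}, {ycol})"] = {"r": float(r), "p": float(rp)}
        out[str(g)] = entry
    return out
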