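"""Group statistics for the volumetric and behavioral measures.

* mixed-design ANOVA with one between-subject factor (group) and one
  two-level within-subject factor (side: left/right bulb), balanced
  designs only -- exactly the design of a three-group, 15-per-group,
  left/right bulb-volume comparison, where the degrees of freedom are
  group (2, 42), side (1, 42) and group x side (2, 42);
* one-way (univariate) ANOVA per variable;
* partial eta squared, related to F by eta_p^2 = F df1 / (F df1 + df2);
* Pearson correlation with Bonferroni correction over m comparisons.

With a two-level within factor, sphericity holds trivially and no
correction is applied.  Unbalanced designs are rejected explicitly rather
than approximated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass
class CorrelationResult:
    r: float
    p_raw: float
    p_bonferroni: float
    n: int


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return F * df1 / (F * df1 + df2)


def _f_result(effect, ss_eff, df_eff, ss_err, df_err) -> AnovaResult:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    F = 0.0 if ms_err == 0 and ms_eff == 0 else ms_eff / ms_err
    p = float(sps.f.sf(F, df_eff, df_err))
    return AnovaResult(effect=effect, F=float(F), df1=df_eff, df2=df_err,
                       p=p, eta_p_sq=partial_eta_sq(F, df_eff, df_err))


def mixed_anova(df, value: str = "volume_mm3", subject: str = "subject_id",
                group: str = "group", within: str = "side") -> list[AnovaResult]:
    """Balanced mixed ANOVA: between factor ``group``, two-level within
    factor ``within``; returns results for group, side and interaction.

    The group effect is tested against the subjects-within-groups error,
    the within and interaction effects against the within-subject error.
    """
    data = df[[subject, group, within, value]].copy()
    sides = sorted(data[within].unique())
    if len(sides) != 2:
        raise ValueError("within factor must have exactly 2 levels")
    groups = sorted(data[group].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a group effect")

    counts = data.groupby([subject, within]).size()
    if (counts != 1).any() or (data.groupby(subject).size() != 2).any():
        raise ValueError("each subject needs exactly one value per side")
    subj_groups = data.groupby(subject)[group].nunique()
    if (subj_groups != 1).any():
        raise ValueError("a subject appears in more than one group")
    n_per_group = data.groupby(group)[subject].nunique()
    if n_per_group.nunique() != 1:
        raise ValueError("unbalanced design: unequal group sizes")
    n = int(n_per_group.iloc[0])
    if n < 2:
        raise ValueError("need >= 2 subjects per group")
    k, s = len(groups), 2

    grand = data[value].mean()
    g_means = data.groupby(group)[value].mean()
    s_means = data.groupby(within)[value].mean()
    cell_means = data.groupby([group, within])[value].mean()
    subj_means = data.groupby(subject)[value].mean()
    subj_group = data.groupby(subject)[group].first()

    ss_group = s * n * float(((g_means - grand) ** 2).sum())
    ss_between_subj = s * float(((subj_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_side = k * n * float(((s_means - grand) ** 2).sum())
    ss_inter = n * sum(
        (cell_means[g, sd] - g_means[g] - s_means[sd] + grand) ** 2
        for g in groups for sd in sides
    )
    resid = data.apply(
        lambda row: row[value]
        - cell_means[row[group], row[within]]
        - subj_means[row[subject]]
        + g_means[subj_group[row[subject]]],
        axis=1,
    )
    ss_within_err = float((resid ** 2).sum())

    df_group, df_subj = k - 1, k * (n - 1)
    df_side, df_inter, df_err = s - 1, (k - 1) * (s - 1), k * (n - 1) * (s - 1)
    return [
        _f_result("group", ss_group, df_group, ss_subj_within, df_subj),
        _f_result(within, ss_side, df_side, ss_within_err, df_err),
        _f_result(f"group x {within}", ss_inter, df_inter, ss_within_err, df_err),
    ]


def oneway_anova(values, groups) -> AnovaResult:
    """Univariate one-way ANOVA of one variable across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    grand = values.mean()
    ss_between = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
                     for g in levels)
    ss_within = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                    for g in levels)
    df1, df2 = len(levels) - 1, len(values) - len(levels)
    return _f_result("group", float(ss_between), df1, float(ss_within), df2)


def pearson_bonferroni(x, y, m: int = 1) -> CorrelationResult:
    """Pearson r with two-sided p (t transform, n-2 df) and Bonferroni
    correction over ``m`` comparisons."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired samples of equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    if m < 1:
        raise ValueError("m must be >= 1")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_raw=float(res.pvalue),
                             p_bonferroni=min(1.0, m * float(res.pvalue)),
                             n=len(x))


def anova_table(results: list[AnovaResult]):
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
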