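"""Mixed and one-way ANOVA against independent oracles, the partial eta
squared identity, and Bonferroni-corrected Pearson correlations."""

import numpy as np
import pandas as pd
import pytest

from olfbulb import (
    CohortConfig,
    generate_cohort,
    mixed_anova,
    oneway_anova,
    partial_eta_sq,
    pearson_bonferroni,
    subject_volumes,
)


def balanced_frame(rng, n=15, k=3, group_shift=(0.0, 0.0, 0.0), side_shift=0.0):
    rows = []
    for gi, g in enumerate(["control", "PD", "NPOD"][:k]):
        for s in range(n):
            sid = f"{g}{s}"
            subj_effect = rng.normal(0, 5)
            for side, sh in (("left", 0.0), ("right", side_shift)):
                rows.append({"subject_id": sid, "group": g, "side": side,
                             "volume_mm3": 50 + group_shift[gi] + subj_effect
                             + sh + rng.normal(0, 2)})
    return pd.DataFrame(rows)


def test_null_data_gives_zero_f():
    rows = [{"subject_id": f"s{i}", "group": g, "side": sd, "volume_mm3": 42.0}
            for i, g in enumerate(["a"] * 3 + ["b"] * 3)
            for sd in ("left", "right")]
    for res in mixed_anova(pd.DataFrame(rows)):
        assert res.F == 0.0
        assert res.eta_p_sq == 0.0


def test_mixed_anova_against_pingouin_oracle(rng):
    pingouin = pytest.importorskip("pingouin")
    df = balanced_frame(rng, n=8, group_shift=(0.0, -6.0, -5.0), side_shift=1.5)
    ours = {r.effect: r for r in mixed_anova(df)}
    theirs = pingouin.mixed_anova(data=df, dv="volume_mm3", within="side",
                                  subject="subject_id", between="group")
    t = theirs.set_index("Source")
    assert ours["group"].F == pytest.approx(float(t.loc["group", "F"]), rel=1e-6)
    assert ours["side"].F == pytest.approx(float(t.loc["side", "F"]), rel=1e-6)
    assert ours["group x side"].F == pytest.approx(float(t.loc["Interaction", "F"]), rel=1e-6)
    assert ours["group"].p == pytest.approx(float(t.loc["group", "p_unc"]), rel=1e-6)


def test_mixed_anova_degrees_of_freedom_canonical(rng):
    df = balanced_frame(rng, n=15)
    res = {r.effect: r for r in mixed_anova(df)}
    assert (res["group"].df1, res["group"].df2) == (2, 42)
    assert (res["side"].df1, res["side"].df2) == (1, 42)
    assert (res["group x side"].df1, res["group x side"].df2) == (2, 42)


def test_ss_decomposition_conserves_total(rng):
    df = balanced_frame(rng, n=6, group_shift=(0, -4, -3), side_shift=2.0)
    results = mixed_anova(df)
    grand = df["volume_mm3"].mean()
    ss_total = float(((df["volume_mm3"] - grand) ** 2).sum())
    # rebuild SS terms from F and dfs is lossy; recompute via effect sizes:
    # eta_p^2 = ss_eff/(ss_eff+ss_err) and F = (ss_eff/df1)/(ss_err/df2)
    # instead verify conservation directly from the definitional pieces
    k, n, s = 3, 6, 2
    g_means = df.groupby("group")["volume_mm3"].mean()
    subj_means = df.groupby("subject_id")["volume_mm3"].mean()
    s_means = df.groupby("side")["volume_mm3"].mean()
    cell = df.groupby(["group", "side"])["volume_mm3"].mean()
    ss_group = s * n * float(((g_means - grand) ** 2).sum())
    ss_subj = s * float(((subj_means - grand) ** 2).sum()) - ss_group
    ss_side = k * n * float(((s_means - grand) ** 2).sum())
    ss_inter = n * sum((cell[g, sd] - g_means[g] - s_means[sd] + grand) ** 2
                       for g in g_means.index for sd in ("left", "right"))
    ss_err = ss_total - ss_group - ss_subj - ss_side - ss_inter
    assert ss_err >= 0
    res = {r.effect: r for r in results}
    # cross-check the F ratios implied by this independent decomposition
    assert res["group"].F == pytest.approx((ss_group / 2) / (ss_subj / (k * (n - 1))), rel=1e-8)
    assert res["side"].F == pytest.approx((ss_side / 1) / (ss_err / (k * (n - 1))), rel=1e-8)


def test_mixed_anova_rejects_bad_designs(rng):
    df = balanced_frame(rng, n=4)
    with pytest.raises(ValueError):
        mixed_anova(df.iloc[:-1])  # missing one side value
    unbalanced = df[df.subject_id != "control0"]
    with pytest.raises(ValueError):
        mixed_anova(unbalanced)
    single = df[df.group == "PD"]
    with pytest.raises(ValueError):
        mixed_anova(single)


def test_planted_volume_effect_detected_with_power():
    """Cohorts with reduced patient bulb volumes: the group effect is
    significant at p < 0.01 in (nearly) every simulated cohort."""
    hits = 0
    for seed in range(5):
        cohort = generate_cohort(CohortConfig(raster_shape=(220, 300),
                                              noise_sd=0.0, seed=100 + seed))
        res = {r.effect: r for r in mixed_anova(subject_volumes(cohort))}
        hits += res["group"].p < 0.01
    assert hits == 5


def test_type_one_error_near_nominal():
    """Null cohorts (equal volume means): the group test rejects at
    roughly the nominal 5% rate."""
    rng = np.random.default_rng(0)
    rejections = 0
    n_sim = 400
    for _ in range(n_sim):
        df = balanced_frame(rng, n=5)
        res = {r.effect: r for r in mixed_anova(df)}
        rejections += res["group"].p < 0.05
    rate = rejections / n_sim
    assert 0.025 <= rate <= 0.08  # binomial CI around 0.05 at 400 sims


@pytest.mark.parametrize("F,df1,df2,expected", [
    (44.51, 2, 42, 0.68),
    (18.49, 2, 42, 0.47),
    (0.0, 2, 42, 0.0),
])
def test_partial_eta_sq_identity(F, df1, df2, expected):
    assert partial_eta_sq(F, df1, df2) == pytest.approx(expected, abs=0.005)


def test_partial_eta_sq_monotone_in_f():
    vals = [partial_eta_sq(f, 2, 42) for f in np.linspace(0, 100, 50)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        partial_eta_sq(-1.0, 2, 42)
    with pytest.raises(ValueError):
        partial_eta_sq(1.0, 0, 42)


def test_oneway_anova_against_scipy(rng):
    from scipy.stats import f_oneway

    groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
    values = rng.normal(0, 1, 30) + np.repeat([0.0, 1.0, 2.0], 10)
    res = oneway_anova(values, groups)
    ref = f_oneway(values[:10], values[10:20], values[20:])
    assert res.F == pytest.approx(ref.statistic, rel=1e-9)
    assert res.p == pytest.approx(ref.pvalue, rel=1e-9)
    assert (res.df1, res.df2) == (2, 27)


def test_pearson_perfect_linear():
    r = pearson_bonferroni([1, 2, 3, 4], [2, 4, 6, 8])
    assert r.r == pytest.approx(1.0)


def test_pearson_matches_definitional_formula(rng):
    x = rng.normal(0, 1, 40)
    y = 0.5 * x + rng.normal(0, 1, 40)
    res = pearson_bonferroni(x, y, m=3)
    r_manual = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
    assert res.r == pytest.approx(r_manual, rel=1e-9)
    assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p_raw))
    assert res.p_bonferroni >= res.p_raw


def test_bonferroni_arithmetic_and_validation():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = pearson_bonferroni(x, y, m=1)
    assert pearson_bonferroni(x, y, m=3).p_bonferroni == pytest.approx(min(1.0, 3 * res.p_raw))
    with pytest.raises(ValueError):
        pearson_bonferroni([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_bonferroni([1, 2], [1, 2])
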