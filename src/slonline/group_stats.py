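"""Condition-contrast inference for the fixed-sequence designs.

Per-subject condition summaries feed a one-way repeated-measures ANOVA on
mean RT with Tukey-Kramer pairwise tests (studentized-range distribution on
the RM error term), a Friedman test on median accuracy with Wilcoxon
signed-rank pairwise tests, independent-cohort difference contrasts
(t / Mann-Whitney with Holm-Bonferroni adjustment), and a Monte-Carlo power
routine that simulates full cohorts through the cascade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from . import seeding
from .designs import DesignSpec, PHASE_STRUCTURED
from .errors import ConfigurationError, EstimationError
from .observer import ObserverParams, make_cohort
from .preprocess import FilterConfig, preprocess

CONDITIONS = ("P1", "P2", "S")


@dataclass(frozen=True)
class ContrastResult:
    """One test: statistic, df, p, effect size, adjustment label."""

    name: str
    statistic: str  # "F" | "chi2" | "q" | "z" | "t" | "U"
    value: float
    df: tuple
    p: float
    effect_size: float | None = None
    effect_size_type: str | None = None
    adjustment: str | None = None


def summarize_conditions(df: pd.DataFrame) -> pd.DataFrame:
    """One row per subject × condition: mean correct RT, median accuracy.

    Mean RT uses correct, RT-valid structured trials.  Accuracy is the
    per-run proportion correct, medianed over runs (RT trims do not change
    accuracy denominators because incorrect trials are retained upstream).
    """
    d = df[df["phase"] == PHASE_STRUCTURED]
    d = d[d["condition"].isin(CONDITIONS)]
    if d.empty:
        raise ConfigurationError("summarize_conditions: no structured trials")
    rt_rows = d[d["rt_valid"]] if "rt_valid" in d.columns else d[d["correct"]]
    mean_rt = rt_rows.groupby(["subject_id", "condition"], observed=True)["rt_s"].agg(
        mean_rt_s="mean", n_trials="size"
    )
    run_acc = d.groupby(["subject_id", "condition", "run"], observed=True)[
        "correct"
    ].mean()
    med_acc = run_acc.groupby(["subject_id", "condition"]).median().rename(
        "median_accuracy"
    )
    out = mean_rt.join(med_acc, how="outer").reset_index()
    empty = out["n_trials"].isna()
    if empty.any():
        warnings.warn(
            "subject x condition cells without valid RT trials: "
            f"{out.loc[empty, ['subject_id', 'condition']].to_records(index=False)}",
            stacklevel=2,
        )
    return out


def _pivot(summaries: pd.DataFrame, value: str) -> pd.DataFrame:
    """Subjects × conditions matrix, complete cases only."""
    wide = summaries.pivot(index="subject_id", columns="condition", values=value)
    missing = [c for c in CONDITIONS if c not in wide.columns]
    if missing:
        raise EstimationError(f"conditions missing entirely: {missing}")
    wide = wide[list(CONDITIONS)]
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping subjects with incomplete cells: {list(wide.index[incomplete])}",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    if len(wide) < 3:
        raise EstimationError("need at least 3 complete subjects")
    return wide


def _paired_d(x: np.ndarray, y: np.ndarray) -> float:
    diff = x - y
    sd = diff.std(ddof=1)
    return float(diff.mean() / sd) if sd > 0 else float("nan")


def rm_anova_rt(summaries: pd.DataFrame):
    """One-way repeated-measures ANOVA on mean RT + Tukey-Kramer pairwise.

    Pairwise q statistics use the RM error mean square; Cohen's d is the
    paired-difference standardized mean.  Returns ``(omnibus, pairwise)``.
    """
    wide = _pivot(summaries, "mean_rt_s")
    n, k = wide.shape
    x = wide.to_numpy()
    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_total = ((x - grand) ** 2).sum()
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    se = np.sqrt(ms_err / n)

    tiny = 1e-12 * max(ss_total, 1e-300)
    if ss_cond <= tiny or ms_err <= tiny:
        # degenerate decompositions: identical conditions give F = 0/0
        # (reported as 0), zero error variance with a real condition effect
        # gives an infinite F
        F = 0.0 if ss_cond <= tiny else float("inf")
        df1, df2 = float(k - 1), float(df_err)
        p = 1.0 if F == 0.0 else 0.0
    else:
        long = wide.reset_index().melt(
            id_vars="subject_id", var_name="condition", value_name="mean_rt_s"
        )
        fit = AnovaRM(
            long, depvar="mean_rt_s", subject="subject_id", within=["condition"]
        ).fit()
        row = fit.anova_table.iloc[0]
        F = float(row["F Value"])
        df1, df2 = float(row["Num DF"]), float(row["Den DF"])
        p = float(row["Pr > F"])

    omnibus = ContrastResult("RT RM-ANOVA", "F", F, (df1, df2), p)
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = CONDITIONS[i], CONDITIONS[j]
            diff = cond_means[i] - cond_means[j]
            q = diff / se if se > 0 else 0.0
            pq = (
                float(sps.studentized_range.sf(abs(q), k, df_err))
                if se > 0
                else 1.0
            )
            pairwise.append(
                ContrastResult(
                    f"RT {ci}-{cj}",
                    "q",
                    float(q),
                    (k, df_err),
                    pq,
                    effect_size=_paired_d(x[:, i], x[:, j]),
                    effect_size_type="cohens_d_paired",
                    adjustment="Tukey-Kramer",
                )
            )
    return omnibus, pairwise


def friedman_accuracy(summaries: pd.DataFrame):
    """Friedman test on median accuracy + pairwise Wilcoxon signed-rank.

    Pairwise effect sizes are rank-biserial r = |z| / sqrt(n).  Returns
    ``(omnibus, pairwise)``.
    """
    wide = _pivot(summaries, "median_accuracy")
    n, k = wide.shape
    cols = [wide[c].to_numpy() for c in CONDITIONS]
    if all((c == cols[0]).all() for c in cols[1:]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = sps.friedmanchisquare(*cols)
    omnibus = ContrastResult("accuracy Friedman", "chi2", float(chi2), (k - 1,), float(p))
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = CONDITIONS[i], CONDITIONS[j]
            diff = cols[i] - cols[j]
            if np.all(diff == 0):
                z, pw = 0.0, 1.0
            else:
                res = sps.wilcoxon(
                    cols[i], cols[j], zero_method="wilcox", method="approx"
                )
                z, pw = float(res.zstatistic), float(res.pvalue)
            pairwise.append(
                ContrastResult(
                    f"accuracy {ci}-{cj}",
                    "z",
                    z,
                    (n,),
                    pw,
                    effect_size=abs(z) / np.sqrt(n),
                    effect_size_type="rank_biserial_r",
                    adjustment="Wilcoxon",
                )
            )
    return omnibus, pairwise


_DIFFS = (("P1", "P2"), ("P2", "S"), ("P1", "S"))


def between_experiment_contrasts(
    summaries_a: pd.DataFrame, summaries_b: pd.DataFrame
) -> list[ContrastResult]:
    """Compare per-subject condition-difference scores across two cohorts.

    RT differences (P1−P2, P2−S, P1−S) by two-sample t tests, accuracy
    differences by Mann-Whitney U; each family Holm-Bonferroni adjusted.
    """
    results = []
    for value, label in (("mean_rt_s", "RT"), ("median_accuracy", "accuracy")):
        wa = _pivot(summaries_a, value)
        wb = _pivot(summaries_b, value)
        if len(wa) < 2 or len(wb) < 2:
            raise EstimationError("need >= 2 subjects per cohort")
        raw = []
        for c1, c2 in _DIFFS:
            da = (wa[c1] - wa[c2]).to_numpy()
            db = (wb[c1] - wb[c2]).to_numpy()
            if label == "RT":
                t, p = sps.ttest_ind(da, db, equal_var=True)
                pooled = np.sqrt(
                    (
                        (len(da) - 1) * da.var(ddof=1)
                        + (len(db) - 1) * db.var(ddof=1)
                    )
                    / (len(da) + len(db) - 2)
                )
                es = (da.mean() - db.mean()) / pooled if pooled > 0 else np.nan
                raw.append(
                    ContrastResult(
                        f"RT {c1}-{c2} A vs B",
                        "t",
                        float(t),
                        (len(da) + len(db) - 2,),
                        float(p),
                        effect_size=float(es),
                        effect_size_type="cohens_d",
                        adjustment="Holm-Bonferroni",
                    )
                )
            else:
                u, p = sps.mannwhitneyu(da, db, alternative="two-sided")
                rb = 1.0 - 2.0 * u / (len(da) * len(db))
                raw.append(
                    ContrastResult(
                        f"accuracy {c1}-{c2} A vs B",
                        "U",
                        float(u),
                        (len(da), len(db)),
                        float(p),
                        effect_size=float(rb),
                        effect_size_type="rank_biserial_r",
                        adjustment="Holm-Bonferroni",
                    )
                )
        adj = multipletests([r.p for r in raw], method="holm")[1]
        for r, pa in zip(raw, adj):
            results.append(
                ContrastResult(
                    r.name, r.statistic, r.value, r.df, float(pa),
                    r.effect_size, r.effect_size_type, r.adjustment,
                )
            )
    return results


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_reject: int
    n_iter: int
    alpha: float
    test: str


def _test_pvalue(summaries: pd.DataFrame, test: str) -> float:
    if test == "rm_anova":
        return rm_anova_rt(summaries)[0].p
    if test == "tukey_p2_vs_s":
        _, pairwise = rm_anova_rt(summaries)
        return next(r.p for r in pairwise if r.name == "RT P2-S")
    if test == "friedman":
        return friedman_accuracy(summaries)[0].p
    raise ConfigurationError(f"unknown test {test!r}")


def mc_power(
    spec: DesignSpec,
    params: ObserverParams,
    n_subjects: int,
    n_iter: int,
    alpha: float = 0.05,
    test: str = "tukey_p2_vs_s",
    seed: int = 0,
    filters: FilterConfig | None = None,
    transform=None,
) -> PowerResult:
    """Monte-Carlo power: fraction of simulated cohorts where ``test`` rejects.

    ``transform`` optionally maps the preprocessed table before
    summarization (e.g. the category-repeating-trial exclusion).  The
    returned CI is a Wilson binomial interval.
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    filters = filters or FilterConfig()
    n_reject = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for it in range(n_iter):
            cohort = make_cohort(
                spec, n_subjects, params, seed=seeding.child_seed(seed, "mc", it)
            )
            table, _ = preprocess(cohort, filters)
            if transform is not None:
                table = transform(table)
            summaries = summarize_conditions(table)
            if _test_pvalue(summaries, test) < alpha:
                n_reject += 1
    lo, hi = proportion_confint(n_reject, n_iter, method="wilson")
    return PowerResult(
        n_reject / n_iter, float(lo), float(hi), n_reject, n_iter, alpha, test
    )
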