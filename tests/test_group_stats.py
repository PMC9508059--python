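"""Condition-contrast tests against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

import slonline as sl

CONDITIONS = ("P1", "P2", "S")


def _summaries(rt=None, acc=None):
    """Build a summary table from subjects x conditions matrices."""
    n = len(rt) if rt is not None else len(acc)
    rows = []
    for i in range(n):
        for j, c in enumerate(CONDITIONS):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "condition": c,
                    "mean_rt_s": rt[i][j] if rt is not None else 0.5,
                    "median_accuracy": acc[i][j] if acc is not None else 0.9,
                    "n_trials": 10,
                }
            )
    return pd.DataFrame(rows)


def rm_anova_oracle(x):
    """One-way repeated-measures ANOVA F by explicit sums-of-squares loops."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (x[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = sum((v - grand) ** 2 for v in x.ravel())
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


def friedman_oracle(x):
    """Friedman chi-square by explicit within-subject rank arithmetic
    (mid-ranks for ties, with the tie correction)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    ranks = np.zeros_like(x)
    tie_factor = 0.0
    for i in range(n):
        row = x[i]
        order = np.argsort(row)
        r = np.empty(k)
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            mid = np.mean([j + m + 1 for m in range(len(tied))])
            for t in tied:
                r[t] = mid
            tie_factor += len(tied) ** 3 - len(tied)
            j += len(tied)
        ranks[i] = r
    rj = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1))) * (rj**2).sum() - 3.0 * n * (k + 1)
    correction = 1.0 - tie_factor / (n * k * (k**2 - 1))
    return chi2 / correction if correction > 0 else 0.0


def mannwhitney_u_oracle(a, b):
    """U statistic by exhaustive pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestSummaries:
    def test_constant_rts(self, preprocessed_exp2):
        table, _ = preprocessed_exp2
        t = table.copy()
        t["rt_s"] = 0.5
        s = sl.summarize_conditions(t)
        assert (s["mean_rt_s"] == 0.5).all()

    def test_hand_computed_means(self):
        rows = []
        rts = {"P1": [0.4, 0.6], "P2": [0.3, 0.5], "S": [0.7, 0.9]}
        for c, vals in rts.items():
            for t, v in enumerate(vals):
                rows.append(
                    dict(session_id="s", subject_id="a", run=0, trial=len(rows),
                         phase="structured", stimulus_id=f"x{len(rows)}",
                         category="A", condition=c, chunk_id="k", repetition=2,
                         iti_ms=500.0, rt_s=v, correct=True, rt_valid=True)
                )
        s = sl.summarize_conditions(pd.DataFrame(rows)).set_index("condition")
        assert s.loc["P1", "mean_rt_s"] == pytest.approx(0.5)
        assert s.loc["P2", "mean_rt_s"] == pytest.approx(0.4)
        assert s.loc["S", "mean_rt_s"] == pytest.approx(0.8)

    def test_priming_cohort_p2_fastest(self, preprocessed_exp2):
        table, _ = preprocessed_exp2
        s = sl.summarize_conditions(table)
        means = s.groupby("condition")["mean_rt_s"].mean()
        assert means["P2"] < means["S"]


class TestRmAnova:
    def test_identical_conditions_f_zero(self):
        rt = [[0.5, 0.5, 0.5], [0.6, 0.6, 0.6], [0.4, 0.4, 0.4], [0.7, 0.7, 0.7]]
        omni, pairwise = sl.rm_anova_rt(_summaries(rt=rt))
        assert omni.value == pytest.approx(0.0, abs=1e-12)
        assert all(r.p == pytest.approx(1.0) for r in pairwise)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        rt = 0.6 + 0.05 * rng.standard_normal((5, 3))
        omni, _ = sl.rm_anova_rt(_summaries(rt=rt))
        f, df1, df2 = rm_anova_oracle(rt)
        assert omni.value == pytest.approx(f, abs=1e-10)
        assert omni.df == (df1, df2)

    def test_tukey_q_and_effect_size(self):
        rng = np.random.default_rng(1)
        rt = 0.6 + 0.02 * rng.standard_normal((6, 3))
        rt[:, 1] -= 0.05  # strong P2 advantage
        _, pairwise = sl.rm_anova_rt(_summaries(rt=rt))
        p2s = next(r for r in pairwise if r.name == "RT P2-S")
        assert p2s.value < 0  # P2 faster
        assert p2s.p < 0.01
        d = (rt[:, 1] - rt[:, 2]).mean() / (rt[:, 1] - rt[:, 2]).std(ddof=1)
        assert p2s.effect_size == pytest.approx(d, abs=1e-12)

    def test_incomplete_design_errors(self):
        s = _summaries(rt=[[0.5, 0.6, 0.7]] * 4)
        with pytest.raises(sl.EstimationError):
            sl.rm_anova_rt(s[s["condition"] != "P1"])


class TestFriedman:
    def test_identical_accuracies_chi2_zero(self):
        acc = [[0.9, 0.9, 0.9]] * 5
        omni, pairwise = sl.friedman_accuracy(_summaries(acc=acc))
        assert omni.value == 0.0
        assert all(r.p == 1.0 for r in pairwise)

    def test_matches_rank_oracle(self):
        acc = [
            [0.90, 0.95, 0.85],
            [0.92, 0.99, 0.91],
            [0.88, 0.90, 0.93],
            [0.94, 0.97, 0.90],
        ]
        omni, _ = sl.friedman_accuracy(_summaries(acc=acc))
        assert omni.value == pytest.approx(friedman_oracle(acc), abs=1e-10)

    def test_wilcoxon_effect_size_is_z_over_sqrt_n(self):
        rng = np.random.default_rng(2)
        acc = np.clip(0.9 + 0.03 * rng.standard_normal((8, 3)), 0, 1)
        acc[:, 1] += 0.05
        _, pairwise = sl.friedman_accuracy(_summaries(acc=acc))
        for r in pairwise:
            assert r.effect_size == pytest.approx(abs(r.value) / np.sqrt(8))


class TestBetweenExperiments:
    def test_identical_cohorts_all_adjusted_p_one(self):
        rng = np.random.default_rng(3)
        rt = 0.6 + 0.02 * rng.standard_normal((6, 3))
        acc = np.clip(0.9 + 0.02 * rng.standard_normal((6, 3)), 0, 1)
        s = _summaries(rt=rt, acc=acc)
        results = sl.between_experiment_contrasts(s, s)
        assert all(r.p >= 0.99 for r in results)

    def test_u_matches_exhaustive_enumeration(self):
        rt_a = [[0.60, 0.55, 0.62], [0.58, 0.50, 0.61], [0.63, 0.54, 0.60]]
        rt_b = [[0.61, 0.60, 0.62], [0.59, 0.58, 0.60], [0.62, 0.63, 0.61]]
        acc_a = [[0.90, 0.97, 0.91], [0.88, 0.96, 0.90], [0.92, 0.99, 0.93]]
        acc_b = [[0.91, 0.92, 0.90], [0.89, 0.90, 0.91], [0.93, 0.92, 0.94]]
        sa = _summaries(rt=rt_a, acc=acc_a)
        sb = _summaries(rt=rt_b, acc=acc_b)
        results = sl.between_experiment_contrasts(sa, sb)
        for c1, c2 in (("P1", "P2"), ("P2", "S"), ("P1", "S")):
            i1, i2 = CONDITIONS.index(c1), CONDITIONS.index(c2)
            da = [row[i1] - row[i2] for row in acc_a]
            db = [row[i1] - row[i2] for row in acc_b]
            expect = mannwhitney_u_oracle(da, db)
            got = next(
                r for r in results if r.name == f"accuracy {c1}-{c2} A vs B"
            )
            assert got.value == pytest.approx(expect, abs=1e-10)

    def test_motor_confound_inflates_p2_s_difference(self):
        """The alternation-priming observer widens the P2-vs-S RT difference
        under the all-alternating design relative to the balanced design."""
        motor = sl.ObserverParams(prime_amp=0.0, motor_amp=0.007)
        a = sl.make_cohort(sl.EXP1A, 8, motor, seed=5)
        b = sl.make_cohort(sl.EXP1B, 8, motor, seed=6)
        sa = sl.summarize_conditions(sl.preprocess(a, sl.FilterConfig())[0])
        sb = sl.summarize_conditions(sl.preprocess(b, sl.FilterConfig())[0])
        wa = sa.pivot(index="subject_id", columns="condition", values="mean_rt_s")
        wb = sb.pivot(index="subject_id", columns="condition", values="mean_rt_s")
        diff_a = (wa["S"] - wa["P2"]).mean()
        diff_b = (wb["S"] - wb["P2"]).mean()
        assert diff_a > diff_b + 0.005

    def test_too_small_cohort_errors(self):
        s1 = _summaries(rt=[[0.5, 0.5, 0.5]] * 4)
        s2 = _summaries(rt=[[0.5, 0.5, 0.5]])
        with pytest.raises((sl.EstimationError, ValueError)):
            sl.between_experiment_contrasts(s1, s2)


class TestMcPower:
    def test_invalid_iterations(self):
        with pytest.raises(sl.ConfigurationError):
            sl.mc_power(sl.EXP1A, sl.ObserverParams(), 5, 0)

    def test_large_effect_saturates(self):
        params = sl.ObserverParams(prime_amp=0.0, motor_amp=0.02, sigma_resid=0.05)
        res = sl.mc_power(sl.EXP1A, params, 6, 10, test="tukey_p2_vs_s", seed=1)
        assert res.power >= 0.9
        assert res.n_iter == 10

    def test_power_increases_with_n(self):
        params = sl.ObserverParams(prime_amp=0.0, motor_amp=0.003)
        lo = sl.mc_power(sl.EXP1A, params, 4, 25, seed=2)
        hi = sl.mc_power(sl.EXP1A, params, 12, 25, seed=2)
        assert hi.power >= lo.power
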