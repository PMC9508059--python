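"""Learning-trajectory inference for the warm-up design.

The RT model is a linear mixed-effects regression estimated by REML:

    rt ~ ln(repetition) * condition + ITI
    random: subject intercept + subject slope on ln(repetition),
            picture intercept, NVAR-class intercept

with condition a three-level factor (reference S) and covariates centered
at their sample means, so the condition dummies are the estimated marginal
means (EMMs) at the average repetition and ITI, and the slope terms are the
per-condition linear trends of RT in ln(repetition).  Pairwise contrasts of
EMMs and trends are z tests with Tukey adjustment through the
studentized-range distribution.  Type-III tests are Wald chi-square on the
fixed-effect covariance (the estimation backend provides no Satterthwaite
degrees of freedom; the df method is labeled in the result).

Pictures are unique to each subject, so their variance component is nested
in subject; the NVAR component is likewise fit at the subject level (see
the methods note for the difference from a globally crossed intercept).

The shape question — does priming grow linearly or logarithmically with
repetition? — is answered on per-subject, per-repetition S−P2 mean RT
differences by an encompassing test: each single-predictor regression
(repetition vs ln(repetition)) is F-tested against the model containing
both, and the shape whose model the combined fit cannot improve upon wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from . import seeding
from .designs import DesignSpec, PHASE_STRUCTURED
from .errors import ConfigurationError, EstimationError
from .observer import ObserverParams, make_cohort
from .preprocess import FilterConfig, preprocess

CONDITIONS = ("S", "P1", "P2")  # S is the reference level

_FE_NAMES = ["Intercept", "cond_P1", "cond_P2", "lrep_c", "int_P1", "int_P2", "iti_c"]


@dataclass(frozen=True)
class TrajectoryModelSpec:
    """Which random-effect structure to fit.

    ``reduced()`` drops the picture and NVAR components — the fallback for
    convergence trouble and the cheap variant for Monte-Carlo loops.
    """

    random_slope: bool = True
    picture_vc: bool = True
    nvar_vc: bool = True
    drop_missing_nvar: bool = True
    reml: bool = True

    @staticmethod
    def full() -> "TrajectoryModelSpec":
        return TrajectoryModelSpec()

    @staticmethod
    def reduced() -> "TrajectoryModelSpec":
        return TrajectoryModelSpec(picture_vc=False, nvar_vc=False)


@dataclass
class TrajectoryFitResult:
    """Fixed effects, type-III table, EMMs/trends and their contrasts."""

    fe_params: pd.Series
    fe_cov: pd.DataFrame
    type3: pd.DataFrame  # term, chi2, df, p
    emm: pd.DataFrame  # condition, emm_s, se
    trends: pd.DataFrame  # condition, trend, se
    emm_contrasts: pd.DataFrame  # contrast, estimate, z, p_tukey
    trend_contrasts: pd.DataFrame
    random_variances: dict
    converged: bool
    df_method: str
    n_obs: int

    def check_consistency(self, atol: float = 1e-10) -> None:
        """EMM trends must equal the condition-specific coefficient sums."""
        b = self.fe_params
        implied = {
            "S": b["lrep_c"],
            "P1": b["lrep_c"] + b["int_P1"],
            "P2": b["lrep_c"] + b["int_P2"],
        }
        for _, row in self.trends.iterrows():
            if abs(row["trend"] - implied[row["condition"]]) > atol:
                raise AssertionError("trend/coefficient inconsistency")


def _analysis_frame(df: pd.DataFrame, spec: TrajectoryModelSpec) -> pd.DataFrame:
    d = df[df["phase"] == PHASE_STRUCTURED]
    d = d[d["condition"].isin(CONDITIONS)]
    d = d[d["repetition"] >= 2]
    d = d[d["rt_valid"]] if "rt_valid" in d.columns else d[d["correct"]]
    if spec.drop_missing_nvar and "nvar" in d.columns:
        d = d[d["nvar"].notna()]
    if d.empty:
        raise EstimationError("no analyzable trials (structured, rep >= 2, correct)")
    d = d.copy()
    d["lrep"] = np.log(d["repetition"].astype(float))
    d["lrep_c"] = d["lrep"] - d["lrep"].mean()
    d["iti_c"] = d["iti_ms"].astype(float) - d["iti_ms"].astype(float).mean()
    d["cond_P1"] = (d["condition"] == "P1").astype(float)
    d["cond_P2"] = (d["condition"] == "P2").astype(float)
    d["int_P1"] = d["cond_P1"] * d["lrep_c"]
    d["int_P2"] = d["cond_P2"] * d["lrep_c"]
    if "nvar" not in d.columns:
        d["nvar"] = 1.0
    d["nvar_f"] = d["nvar"].astype(int).astype(str)
    return d


def _tukey_p(z: float, k: int = 3) -> float:
    """Two-sided Tukey-adjusted p for one of k(k-1)/2 pairwise z statistics."""
    return float(sps.studentized_range.sf(abs(z) * np.sqrt(2.0), k, 1e7))


def _wald_chi2(beta: pd.Series, cov: pd.DataFrame, names: list[str]):
    b = beta[names].to_numpy()
    V = cov.loc[names, names].to_numpy()
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(names)
    return chi2, df, float(sps.chi2.sf(chi2, df))


def fit_rt_trajectory(
    df: pd.DataFrame, spec: TrajectoryModelSpec | None = None
) -> TrajectoryFitResult:
    """REML mixed-model fit of the RT learning trajectory.

    Raises :class:`EstimationError` on non-convergence, with the advice to
    retry under ``TrajectoryModelSpec.reduced()`` (drop the picture/NVAR
    components) or without the random slope — the standard reduction path
    when a maximal model cannot be estimated.
    """
    spec = spec or TrajectoryModelSpec.full()
    d = _analysis_frame(df, spec)
    if d["condition"].nunique() < 3:
        raise EstimationError("need all three conditions present")

    re_formula = "1 + lrep_c" if spec.random_slope else "1"
    vc = {}
    if spec.picture_vc:
        vc["picture"] = "0 + C(stimulus_id)"
    if spec.nvar_vc and d["nvar_f"].nunique() > 1:
        vc["nvar"] = "0 + C(nvar_f)"
    formula = "rt_s ~ cond_P1 + cond_P2 + lrep_c + int_P1 + int_P2 + iti_c"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM.from_formula(
            formula,
            groups="subject_id",
            re_formula=re_formula,
            vc_formula=vc or None,
            data=d,
        )
        res = None
        last_err = None
        # lbfgs is fast but stalls when a variance component sits on the
        # boundary; powell is the robust (derivative-free) fallback
        for method in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=spec.reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as err:
                last_err = err
                continue
            res = cand
            if getattr(cand, "converged", True):
                break
    if res is None:
        raise EstimationError(
            f"mixed model failed ({last_err}); retry with "
            "TrajectoryModelSpec.reduced() or random_slope=False"
        ) from last_err
    if not getattr(res, "converged", True):
        raise EstimationError(
            "mixed model did not converge; retry with "
            "TrajectoryModelSpec.reduced() or random_slope=False"
        )

    beta = res.fe_params.copy()
    beta.index = pd.Index([n if n != "Intercept" else "Intercept" for n in beta.index])
    k_fe = len(beta)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k_fe, :k_fe], index=beta.index, columns=beta.index
    )

    type3 = pd.DataFrame(
        [
            ("repetition", *_wald_chi2(beta, cov, ["lrep_c"])),
            ("condition", *_wald_chi2(beta, cov, ["cond_P1", "cond_P2"])),
            ("iti", *_wald_chi2(beta, cov, ["iti_c"])),
            ("interaction", *_wald_chi2(beta, cov, ["int_P1", "int_P2"])),
        ],
        columns=["term", "chi2", "df", "p"],
    )

    def _lincomb(weights: dict):
        w = np.array([weights.get(n, 0.0) for n in beta.index])
        est = float(w @ beta.to_numpy())
        se = float(np.sqrt(w @ cov.to_numpy() @ w))
        return est, se

    emm_rows, trend_rows = [], []
    emm_w = {
        "S": {"Intercept": 1.0},
        "P1": {"Intercept": 1.0, "cond_P1": 1.0},
        "P2": {"Intercept": 1.0, "cond_P2": 1.0},
    }
    trend_w = {
        "S": {"lrep_c": 1.0},
        "P1": {"lrep_c": 1.0, "int_P1": 1.0},
        "P2": {"lrep_c": 1.0, "int_P2": 1.0},
    }
    for c in CONDITIONS:
        est, se = _lincomb(emm_w[c])
        emm_rows.append((c, est, se))
        est, se = _lincomb(trend_w[c])
        trend_rows.append((c, est, se))
    emm = pd.DataFrame(emm_rows, columns=["condition", "emm_s", "se"])
    trends = pd.DataFrame(trend_rows, columns=["condition", "trend", "se"])

    def _contrasts(weight_map):
        rows = []
        for c1, c2 in (("S", "P1"), ("S", "P2"), ("P1", "P2")):
            w = {
                k: weight_map[c1].get(k, 0.0) - weight_map[c2].get(k, 0.0)
                for k in set(weight_map[c1]) | set(weight_map[c2])
            }
            est, se = _lincomb(w)
            z = est / se if se > 0 else 0.0
            rows.append((f"{c1}-{c2}", est, se, z, _tukey_p(z)))
        return pd.DataFrame(
            rows, columns=["contrast", "estimate", "se", "z", "p_tukey"]
        )

    result = TrajectoryFitResult(
        fe_params=beta,
        fe_cov=cov,
        type3=type3,
        emm=emm,
        trends=trends,
        emm_contrasts=_contrasts(emm_w),
        trend_contrasts=_contrasts(trend_w),
        random_variances={
            "subject": res.cov_re.to_dict() if hasattr(res.cov_re, "to_dict") else {},
            "vc": dict(zip(model.exog_vc.names, np.atleast_1d(res.vcomp)))
            if vc
            else {},
            "residual": float(res.scale),
        },
        converged=True,
        df_method="wald-chi2 (asymptotic z)",
        n_obs=len(d),
    )
    result.check_consistency()
    return result


@dataclass
class AccuracyFitResult:
    fe_table: pd.DataFrame  # term-level coefficients: estimate, sd, z
    type3: pd.DataFrame  # term, chi2, df, p (diagonal Wald approximation)
    method: str


def fit_accuracy_glmm(df: pd.DataFrame, spec: TrajectoryModelSpec | None = None):
    """Binomial mixed model for correctness.

    Fixed effects ln(repetition), condition, interaction, ITI; random
    subject and picture intercepts.  Estimated by variational Bayes
    (mean-field); the type-III table is a Wald chi-square built from the
    posterior standard deviations and is labeled as such.
    """
    spec = spec or TrajectoryModelSpec.full()
    d = df[df["phase"] == PHASE_STRUCTURED]
    d = d[d["condition"].isin(CONDITIONS)]
    d = d[d["repetition"] >= 2]
    if d.empty:
        raise EstimationError("no analyzable trials")
    d = d.copy()
    d["y"] = d["correct"].astype(float)
    if d["y"].nunique() < 2:
        raise EstimationError(
            "correctness has no variation (all correct or all incorrect); "
            "the binomial model is not estimable"
        )
    d["lrep_c"] = np.log(d["repetition"].astype(float))
    d["lrep_c"] -= d["lrep_c"].mean()
    # ITI in seconds: keeps the covariate on a unit scale, which the
    # variational optimizer needs to make progress
    d["iti_c"] = (d["iti_ms"].astype(float) - d["iti_ms"].astype(float).mean()) / 1000.0
    d["cond_P1"] = (d["condition"] == "P1").astype(float)
    d["cond_P2"] = (d["condition"] == "P2").astype(float)
    d["int_P1"] = d["cond_P1"] * d["lrep_c"]
    d["int_P2"] = d["cond_P2"] * d["lrep_c"]

    vc_formulas = {"subject": "0 + C(subject_id)"}
    if spec.picture_vc:
        vc_formulas["picture"] = "0 + C(stimulus_id)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = BinomialBayesMixedGLM.from_formula(
                "y ~ cond_P1 + cond_P2 + lrep_c + int_P1 + int_P2 + iti_c",
                vc_formulas,
                d,
            )
            res = model.fit_vb()
        except Exception as err:  # separation, singular design, ...
            raise EstimationError(f"binomial mixed model failed: {err}") from err

    names = model.exog_names
    est = pd.Series(res.fe_mean, index=names)
    sd = pd.Series(res.fe_sd, index=names)
    fe = pd.DataFrame({"estimate": est, "sd": sd, "z": est / sd})

    def _term(cols):
        z2 = float(((est[cols] / sd[cols]) ** 2).sum())
        return z2, len(cols), float(sps.chi2.sf(z2, len(cols)))

    type3 = pd.DataFrame(
        [
            ("repetition", *_term(["lrep_c"])),
            ("condition", *_term(["cond_P1", "cond_P2"])),
            ("iti", *_term(["iti_c"])),
            ("interaction", *_term(["int_P1", "int_P2"])),
        ],
        columns=["term", "chi2", "df", "p"],
    )
    return AccuracyFitResult(
        fe_table=fe, type3=type3, method="mean-field VB; diagonal Wald chi2"
    )


# --------------------------------------------------------------- encompassing
@dataclass
class SP2ComparisonResult:
    """Linear-vs-logarithmic comparison of the S−P2 learning curve."""

    differences: pd.DataFrame  # subject_id, repetition, diff_s
    r2_linear: float
    r2_log: float
    r2_combined: float
    f_linear: float  # model F of diff ~ repetition
    f_log: float
    p_linear: float
    p_log: float
    f_lin_vs_comb: float
    p_lin_vs_comb: float
    f_log_vs_comb: float
    p_log_vs_comb: float
    verdict: str  # "log" | "linear" | "indeterminate"


def sp2_differences(df: pd.DataFrame) -> pd.DataFrame:
    """Per subject × repetition mean S RT minus mean P2 RT (filtered trials)."""
    d = df[df["phase"] == PHASE_STRUCTURED]
    d = d[d["repetition"] >= 2]
    d = d[d["rt_valid"]] if "rt_valid" in d.columns else d[d["correct"]]
    means = (
        d[d["condition"].isin(("S", "P2"))]
        .groupby(["subject_id", "repetition", "condition"], observed=True)["rt_s"]
        .mean()
        .unstack("condition")
    )
    if "S" not in means.columns or "P2" not in means.columns:
        raise EstimationError("need both S and P2 trials")
    out = (means["S"] - means["P2"]).dropna().rename("diff_s").reset_index()
    return out


def sp2_encompassing(data: pd.DataFrame, alpha: float = 0.05) -> SP2ComparisonResult:
    """Encompassing test of repetition vs ln(repetition) as the predictor.

    ``data`` is either a trial table (differences are computed first) or a
    precomputed difference table with columns ``repetition`` and ``diff_s``.
    Each nested model is F-tested against the model containing both
    predictors; the verdict is the shape whose model the combined fit does
    not significantly improve while the rival's is rejected.
    """
    diffs = data if "diff_s" in data.columns else sp2_differences(data)
    if diffs["repetition"].nunique() < 3:
        raise EstimationError("need >= 3 distinct repetition values")
    d = diffs.copy()
    d["rep"] = d["repetition"].astype(float)
    d["lrep"] = np.log(d["rep"])

    if float(d["diff_s"].std()) < 1e-14:
        # flat difference curve: both slopes are zero and neither shape is
        # distinguishable
        return SP2ComparisonResult(
            differences=diffs, r2_linear=0.0, r2_log=0.0, r2_combined=0.0,
            f_linear=0.0, f_log=0.0, p_linear=1.0, p_log=1.0,
            f_lin_vs_comb=0.0, p_lin_vs_comb=1.0,
            f_log_vs_comb=0.0, p_log_vs_comb=1.0, verdict="indeterminate",
        )

    m_lin = smf.ols("diff_s ~ rep", d).fit()
    m_log = smf.ols("diff_s ~ lrep", d).fit()
    m_comb = smf.ols("diff_s ~ rep + lrep", d).fit()
    if m_comb.rsquared < max(m_lin.rsquared, m_log.rsquared) - 1e-12:
        raise AssertionError("combined model fits worse than a nested model")

    f_lc, p_lc, _ = m_comb.compare_f_test(m_lin)
    f_gc, p_gc, _ = m_comb.compare_f_test(m_log)
    lin_rejected = p_lc < alpha
    log_rejected = p_gc < alpha
    if lin_rejected and not log_rejected:
        verdict = "log"
    elif log_rejected and not lin_rejected:
        verdict = "linear"
    else:
        verdict = "indeterminate"
    return SP2ComparisonResult(
        differences=diffs,
        r2_linear=float(m_lin.rsquared),
        r2_log=float(m_log.rsquared),
        r2_combined=float(m_comb.rsquared),
        f_linear=float(m_lin.fvalue),
        f_log=float(m_log.fvalue),
        p_linear=float(m_lin.f_pvalue),
        p_log=float(m_log.f_pvalue),
        f_lin_vs_comb=float(f_lc),
        p_lin_vs_comb=float(p_lc),
        f_log_vs_comb=float(f_gc),
        p_log_vs_comb=float(p_gc),
        verdict=verdict,
    )


def lmm_power(
    spec: DesignSpec,
    params: ObserverParams,
    n_subjects: int,
    n_iter: int,
    alpha: float = 0.05,
    seed: int = 0,
    filters: FilterConfig | None = None,
    model_spec: TrajectoryModelSpec | None = None,
):
    """Monte-Carlo power of the log(repetition) × condition interaction test.

    Simulates cohorts, refits the trajectory model and reports the fraction
    of interaction rejections at ``alpha`` with a Wilson binomial CI.
    """
    from .group_stats import PowerResult  # shared result container

    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    filters = filters or FilterConfig(sd_multiplier=2.0)
    model_spec = model_spec or TrajectoryModelSpec.full()
    n_reject = 0
    n_done = 0
    for it in range(n_iter):
        cohort = make_cohort(
            spec, n_subjects, params, seed=seeding.child_seed(seed, "lmm", it)
        )
        table, _ = preprocess(cohort, filters)
        try:
            fit = fit_rt_trajectory(table, model_spec)
        except EstimationError:
            continue  # non-converged replicate contributes nothing
        n_done += 1
        p = float(fit.type3.loc[fit.type3["term"] == "interaction", "p"].iloc[0])
        if p < alpha:
            n_reject += 1
    if n_done == 0:
        raise EstimationError("no replicate converged")
    lo, hi = proportion_confint(n_reject, n_done, method="wilson")
    return PowerResult(
        n_reject / n_done, float(lo), float(hi), n_reject, n_done, alpha,
        "lmm_interaction",
    )
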