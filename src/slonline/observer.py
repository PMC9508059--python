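"""Synthetic observer: forward model for RT and accuracy streams.

The generator mirrors the structure the downstream mixed-effects analysis
assumes.  For a structured trial of subject *i*, picture *p*, condition *c*
at chunk repetition *r*:

    RT = beta0 + b_i + (beta_rep + s_i)·ln(r) + b_p + beta_iti·(ITI − 500)
         − prime_amp·f(r)·[c = P2] + anticip_amp·f(r)·[c = P1]
         − motor_amp·ln(1 + exposure)·[response category alternates]
         + nvar offset + Normal(0, sigma_resid),   truncated below at 50 ms

with subject intercepts b_i ~ N(0, sd_subject_int²), subject log-repetition
slopes s_i ~ N(0, sd_subject_slope²) and picture intercepts
b_p ~ N(0, sd_picture²).  The learning-shape f(r) is ln(r) by default; a
linear alternative (scaled so the endpoint effect matches the logarithmic
curve) exists to exercise shape-discrimination tests.  Warm-up trials
receive no repetition or condition terms.

The motor term is the procedural-priming confound: responses that alternate
category relative to the previous trial get faster with accumulated
exposure (trials seen so far in the session), regardless of the pair
structure.  Correctness is an independent Bernoulli lapse process, optionally
condition-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seeding
from .designs import (
    CONDITION_P1,
    CONDITION_P2,
    DesignSpec,
    PHASE_STRUCTURED,
    TRIAL_COLUMNS,
    generate_session,
    trials_to_frame,
)
from .errors import ConfigurationError

RESPONSE_COLUMNS = TRIAL_COLUMNS + ["rt_s", "correct"]

RT_FLOOR_S = 0.05


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of the synthetic subject.

    Units are seconds unless noted.  Defaults are calibrated to the scale of
    human serial-categorization data: ~0.6 s grand mean, ~10 % residual
    noise, a priming amplitude that separates the P2 and S learning trends
    by ≈5 ms per ln-unit of repetition, and a small positive common slope so
    the control condition drifts by ≈+1 ms per ln-unit.
    """

    beta0: float = 0.6
    beta_rep: float = 0.001          # fixed mean slope on ln(repetition)
    sd_subject_int: float = 0.08
    sd_subject_slope: float = 0.002
    sd_picture: float = 0.02
    beta_iti: float = 2e-5           # s of RT per ms of ITI beyond 500 ms
    prime_amp: float = 0.005         # P2 RT reduction per f(repetition)
    anticip_amp: float = 0.0         # P1 RT change per f(repetition)
    motor_amp: float = 0.0           # alternation-priming confound amplitude
    sigma_resid: float = 0.1
    lapse_rate: float = 0.06
    lapse_by_condition: dict | None = None  # optional overrides, e.g. {"P2": 0.04}
    nvar_effects: tuple[float, float, float] = (0.02, 0.02, 0.04)
    learning_shape: str = "log"      # "log" | "linear"

    def __post_init__(self):
        for name in ("sd_subject_int", "sd_subject_slope", "sd_picture", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.lapse_rate < 1:
            raise ConfigurationError("lapse_rate must be in [0, 1)")
        if self.lapse_by_condition:
            for k, v in self.lapse_by_condition.items():
                if not 0 <= v < 1:
                    raise ConfigurationError(f"lapse for {k} must be in [0, 1)")
        if len(self.nvar_effects) != 3:
            raise ConfigurationError("nvar_effects must give offsets for classes 2-4")
        if self.learning_shape not in ("log", "linear"):
            raise ConfigurationError("learning_shape must be 'log' or 'linear'")

    def lapse_for(self, condition: str) -> float:
        if self.lapse_by_condition and condition in self.lapse_by_condition:
            return self.lapse_by_condition[condition]
        return self.lapse_rate


def _shape(rep: np.ndarray, kind: str) -> np.ndarray:
    """Learning-curve shape f(rep) for rep >= 1.

    "linear" is scaled so the effect at the largest repetition equals the
    logarithmic curve's, keeping total effect sizes comparable between
    shapes.
    """
    rep = np.asarray(rep, dtype=float)
    if kind == "log":
        return np.log(np.maximum(rep, 1.0))
    rmax = rep.max() if rep.size else 1.0
    scale = np.log(rmax) / (rmax - 1.0) if rmax > 1 else 0.0
    return (np.maximum(rep, 1.0) - 1.0) * scale


def simulate_responses(
    trials: pd.DataFrame, params: ObserverParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach simulated ``rt_s`` and ``correct`` columns to a trial table.

    The table may span several subjects and runs; rows must be in
    presentation order within each (subject, run).
    """
    if not isinstance(params, ObserverParams):
        raise ConfigurationError("params must be an ObserverParams instance")
    df = trials.copy()
    if df.empty:
        df["rt_s"] = pd.Series(dtype=float)
        df["correct"] = pd.Series(dtype=bool)
        return df

    run_key = df["subject_id"].astype(str) + "\x1f" + df["run"].astype(str)
    order_ok = df.groupby(run_key, sort=False)["trial"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not order_ok.all():
        raise ConfigurationError("trials must be ordered by trial index within runs")

    n = len(df)
    subjects = df["subject_id"].unique()
    pictures = df["stimulus_id"].unique()
    b_int = dict(zip(subjects, rng.normal(0.0, params.sd_subject_int, len(subjects))))
    b_slope = dict(
        zip(subjects, rng.normal(0.0, params.sd_subject_slope, len(subjects)))
    )
    b_pic = dict(zip(pictures, rng.normal(0.0, params.sd_picture, len(pictures))))

    lapse = df["condition"].map(params.lapse_for).to_numpy(dtype=float)
    correct = rng.random(n) >= lapse

    # NVAR offsets from the correctness stream (previous trial within run)
    prev_correct = pd.Series(correct, index=df.index).groupby(run_key).shift(1)
    offs = np.asarray(params.nvar_effects, dtype=float)
    nvar_off = np.zeros(n)
    has_prev = prev_correct.notna().to_numpy()
    pc = np.ones(n, dtype=bool)
    pc[has_prev] = prev_correct.to_numpy()[has_prev].astype(bool)
    nvar = 1 + (~pc).astype(int) + 2 * (~correct).astype(int)  # 1..4
    mask = has_prev & (nvar > 1)
    nvar_off[mask] = offs[nvar[mask] - 2]

    structured = (df["phase"] == PHASE_STRUCTURED).to_numpy()
    rep = df["repetition"].to_numpy(dtype=float)
    lrep = np.where(structured, np.log(np.maximum(rep, 1.0)), 0.0)
    frep = np.where(structured, _shape(np.maximum(rep, 1.0), params.learning_shape), 0.0)

    is_p1 = (df["condition"] == CONDITION_P1).to_numpy() & structured
    is_p2 = (df["condition"] == CONDITION_P2).to_numpy() & structured

    prev_cat = df.groupby(run_key, sort=False)["category"].shift(1)
    alternates = prev_cat.notna().to_numpy() & (
        prev_cat.to_numpy() != df["category"].to_numpy()
    )
    exposure = df.groupby("subject_id", sort=False).cumcount().to_numpy(dtype=float)
    g = np.log1p(exposure)

    rt = (
        params.beta0
        + df["subject_id"].map(b_int).to_numpy()
        + df["subject_id"].map(b_slope).to_numpy() * lrep
        + params.beta_rep * lrep
        + df["stimulus_id"].map(b_pic).to_numpy()
        + params.beta_iti * (df["iti_ms"].to_numpy(dtype=float) - 500.0)
        - params.prime_amp * frep * is_p2
        + params.anticip_amp * frep * is_p1
        - params.motor_amp * g * alternates
        + nvar_off
    )
    if params.sigma_resid > 0:
        rt = rt + rng.normal(0.0, params.sigma_resid, n)
    df["rt_s"] = np.maximum(rt, RT_FLOOR_S)
    df["correct"] = correct
    return df


def make_cohort(
    spec: DesignSpec,
    n_subjects: int,
    params: ObserverParams,
    seed: int,
    subject_prefix: str = "sub",
) -> pd.DataFrame:
    """Simulate a cohort: sequences plus responses for ``n_subjects``.

    Each subject draws design and response randomness from substreams keyed
    on (stage, subject), so the table is reproducible under ``seed`` and a
    given subject's data do not depend on the cohort size.
    """
    if n_subjects < 0:
        raise ConfigurationError("n_subjects must be >= 0")
    frames = []
    for i in range(n_subjects):
        sid = f"{subject_prefix}{i:03d}"
        design_rng = seeding.substream(seed, "design", i)
        obs_rng = seeding.substream(seed, "observe", i)
        runs = generate_session(spec, sid, design_rng)
        frames.append(simulate_responses(trials_to_frame(runs), params, obs_rng))
    if not frames:
        return pd.DataFrame(columns=RESPONSE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RESPONSE_COLUMNS]
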