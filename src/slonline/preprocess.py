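"""Trial-exclusion cascade and analysis coding.

The cascade applies, in this fixed order:

1. subject exclusion — session-wide accuracy strictly below the minimum
   (60 %) removes all of a subject's rows;
2. run exclusion — runs with accuracy strictly below the minimum (80 %);
3. NVAR coding from the current/previous correctness within each run;
4. fast-RT trim — responses faster than 200 ms;
5. slow-RT trim — responses slower than mean + k·SD, with the reference
   mean/SD computed per subject over that subject's correct structured
   trials (k = 3 for the 12-stimulus designs, 2 for the warm-up design);
6. warm-up removal;
7. first-presentation removal — repetition 1 carries no learning signal.

Incorrect responses are retained (flagged ``rt_valid = False``) so accuracy
analyses keep their denominators; accuracies are always computed before the
RT trims.  An :class:`ExclusionReport` gives per-rule counts and
percentages of the input total, plus a per-subject breakdown.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import PHASE_STRUCTURED, PHASE_WARMUP
from .errors import ConfigurationError, SchemaError

RULES = [
    "low_accuracy_subject",
    "low_accuracy_run",
    "fast_rt",
    "slow_rt",
    "warmup",
    "first_presentation",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the exclusion cascade.

    ``sd_multiplier`` is 3 for the exp1a/exp1b designs and 2 for exp2 (the
    warm-up period removes the early-run RT drop, permitting the stricter
    trim).  ``trim_grouping`` selects the reference population of the slow
    trim: "subject" (default), "subject_run" or "subject_condition".
    ``drop_first_k_trials`` affects only the visualization helper, never
    statistics.
    """

    sd_multiplier: float = 3.0
    min_rt_s: float = 0.200
    run_accuracy_min: float = 0.80
    subject_accuracy_min: float = 0.60
    drop_first_presentations: bool = True
    drop_first_k_trials: int = 3
    drop_warmup: bool = True
    trim_grouping: str = "subject"

    def __post_init__(self):
        if self.sd_multiplier <= 0:
            raise ConfigurationError("sd_multiplier must be > 0")
        if not 0 < self.run_accuracy_min <= 1:
            raise ConfigurationError("run_accuracy_min must be in (0, 1]")
        if not 0 < self.subject_accuracy_min <= 1:
            raise ConfigurationError("subject_accuracy_min must be in (0, 1]")
        if self.min_rt_s < 0:
            raise ConfigurationError("min_rt_s must be >= 0")
        if self.trim_grouping not in ("subject", "subject_run", "subject_condition"):
            raise ConfigurationError(f"bad trim_grouping {self.trim_grouping!r}")


FILTERS_EXP1 = FilterConfig(sd_multiplier=3.0)
FILTERS_EXP2 = FilterConfig(sd_multiplier=2.0)


def filters_for(design_name: str) -> FilterConfig:
    return FILTERS_EXP2 if design_name == "exp2" else FILTERS_EXP1


@dataclass
class ExclusionReport:
    """Auditable account of the cascade: counts per rule, of ``n_input``."""

    n_input: int
    removed: dict = field(default_factory=dict)
    per_subject: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def percentages(self) -> dict:
        if self.n_input == 0:
            return {k: 0.0 for k in self.removed}
        return {k: 100.0 * v / self.n_input for k, v in self.removed.items()}

    @property
    def overall_percentage(self) -> float:
        return 0.0 if self.n_input == 0 else 100.0 * self.n_removed / self.n_input

    def add(self, rule: str, frame_removed: pd.DataFrame) -> None:
        self.removed[rule] = self.removed.get(rule, 0) + len(frame_removed)
        if len(frame_removed):
            for sid, cnt in frame_removed["subject_id"].value_counts().items():
                self.per_subject.setdefault(sid, {}).setdefault(rule, 0)
                self.per_subject[sid][rule] += int(cnt)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "removed": dict(self.removed),
            "percentages": self.percentages,
            "overall_percentage": self.overall_percentage,
            "per_subject": self.per_subject,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def __str__(self) -> str:
        lines = [f"trials in: {self.n_input}"]
        for rule in RULES:
            if rule in self.removed:
                lines.append(
                    f"  {rule:>22}: {self.removed[rule]:6d}"
                    f" ({self.percentages[rule]:.2f}%)"
                )
        lines.append(
            f"  {'total removed':>22}: {self.n_removed:6d}"
            f" ({self.overall_percentage:.2f}%)"
        )
        return "\n".join(lines)


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table is missing columns {missing}")


def exclude_subjects(df: pd.DataFrame, config: FilterConfig):
    """Drop subjects whose session-wide accuracy is below the minimum."""
    _require(df, ["subject_id", "correct"])
    if df.empty:
        raise ConfigurationError("exclude_subjects: empty table")
    acc = df.groupby("subject_id")["correct"].mean()
    bad = set(acc[acc < config.subject_accuracy_min].index)
    removed = df[df["subject_id"].isin(bad)]
    return df[~df["subject_id"].isin(bad)], removed


def exclude_runs(df: pd.DataFrame, config: FilterConfig):
    """Drop subject-runs whose accuracy is below the minimum."""
    _require(df, ["subject_id", "run", "correct"])
    if df.empty:
        return df, df
    acc = df.groupby(["subject_id", "run"])["correct"].mean()
    bad = acc[acc < config.run_accuracy_min].index
    key = pd.MultiIndex.from_frame(df[["subject_id", "run"]])
    mask = key.isin(bad)
    return df[~mask], df[mask]


def code_nvar(df: pd.DataFrame) -> pd.DataFrame:
    """Score each trial 1-4 from (previous, current) correctness.

    1 = both correct, 2 = previous wrong / current right, 3 = previous
    right / current wrong, 4 = both wrong.  A run's first trial has no
    predecessor and gets a missing code.
    """
    _require(df, ["subject_id", "run", "trial", "correct"])
    if "nvar" in df.columns:
        # already coded; recoding after row removal would corrupt the codes,
        # which must reflect the actual presentation stream
        return df.copy()
    out = df.copy()
    if out.empty:
        out["nvar"] = pd.Series(dtype=float)
        return out
    run_key = out["subject_id"].astype(str) + "\x1f" + out["run"].astype(str)
    ordered = out.groupby(run_key, sort=False)["trial"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not ordered.all():
        raise SchemaError("code_nvar: rows must be ordered by subject, run, trial")
    prev = out.groupby(run_key, sort=False)["correct"].shift(1)
    miss = prev.isna().to_numpy()
    prev_b = np.ones(len(out), dtype=bool)
    prev_b[~miss] = prev.to_numpy()[~miss].astype(bool)
    cur = out["correct"].to_numpy().astype(bool)
    nvar = 1.0 + (~prev_b).astype(float) + 2.0 * (~cur).astype(float)
    nvar[miss] = np.nan
    out["nvar"] = nvar
    return out


def trim_rts(df: pd.DataFrame, config: FilterConfig):
    """Remove anticipatory (< 200 ms) and outlying slow responses.

    The slow threshold is mean + k·SD of each reference group's *correct
    structured* RTs.  Incorrect trials that survive trimming are flagged
    ``rt_valid = False`` — usable for accuracy, never for mean RTs.
    """
    _require(df, ["subject_id", "rt_s", "correct", "phase"])
    if "rt_valid" in df.columns:
        # already trimmed: recomputing mean + k*SD on trimmed data would
        # shrink the threshold and trim again; the cascade is idempotent
        empty = df.iloc[0:0]
        return df.copy(), empty, empty
    out = df.copy()
    fast_mask = out["rt_s"] < config.min_rt_s
    fast = out[fast_mask]
    out = out[~fast_mask]

    group_cols = {
        "subject": ["subject_id"],
        "subject_run": ["subject_id", "run"],
        "subject_condition": ["subject_id", "condition"],
    }[config.trim_grouping]
    ref = out[(out["correct"]) & (out["phase"] == PHASE_STRUCTURED)]
    stats = ref.groupby(group_cols)["rt_s"].agg(["mean", "std"])
    thresh = stats["mean"] + config.sd_multiplier * stats["std"]
    limit = (
        out[group_cols]
        .merge(
            thresh.rename("limit").reset_index(), how="left", on=group_cols
        )["limit"]
        .to_numpy()
    )
    slow_mask = out["rt_s"].to_numpy() > limit  # NaN limit -> never trimmed
    slow_mask = np.where(np.isnan(limit), False, slow_mask)
    slow = out[slow_mask]
    out = out[~slow_mask]
    out = out.copy()
    out["rt_valid"] = out["correct"].astype(bool)
    return out, fast, slow


def drop_warmup(df: pd.DataFrame):
    mask = df["phase"] == PHASE_WARMUP
    return df[~mask], df[mask]


def drop_first_presentations(df: pd.DataFrame):
    """Remove structured trials with repetition number 1 (no learning yet)."""
    _require(df, ["phase", "repetition"])
    mask = (df["phase"] == PHASE_STRUCTURED) & (df["repetition"] == 1)
    return df[~mask], df[mask]


def drop_category_repeating_trials(df: pd.DataFrame):
    """Remove trials whose category repeats the previous trial's category.

    This is the motor-confound reanalysis: category-repeating trials occur
    only at chunk junctions (P1 and S conditions) in the all-alternating
    design, so removing them equates response-alternation rates across
    conditions.  Returns ``(kept, fraction_removed)``.
    """
    _require(df, ["subject_id", "run", "category"])
    if df.empty:
        return df, 0.0
    run_key = df["subject_id"].astype(str) + "\x1f" + df["run"].astype(str)
    prev = df.groupby(run_key, sort=False)["category"].shift(1)
    mask = prev.notna() & (prev == df["category"])
    return df[~mask], float(mask.mean())


def preprocess(df: pd.DataFrame, config: FilterConfig):
    """Run the full cascade; returns ``(table, ExclusionReport)``."""
    report = ExclusionReport(n_input=len(df))
    out, removed = exclude_subjects(df, config)
    report.add("low_accuracy_subject", removed)
    out, removed = exclude_runs(out, config)
    report.add("low_accuracy_run", removed)
    out = code_nvar(out)
    out, fast, slow = trim_rts(out, config)
    report.add("fast_rt", fast)
    report.add("slow_rt", slow)
    if config.drop_warmup:
        out, removed = drop_warmup(out)
        report.add("warmup", removed)
    if config.drop_first_presentations:
        out, removed = drop_first_presentations(out)
        report.add("first_presentation", removed)
    return out.reset_index(drop=True), report


def learning_curve(df: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Per-condition, per-repetition mean RT for visualization.

    Drops the first ``drop_first_k_trials`` trials of each run (noise at run
    onset); this helper never feeds the statistics.
    """
    config = config or FilterConfig()
    d = df[df["phase"] == PHASE_STRUCTURED]
    if "rt_valid" in d.columns:
        d = d[d["rt_valid"]]
    else:
        d = d[d["correct"]]
    run_key = d["subject_id"].astype(str) + "\x1f" + d["run"].astype(str)
    rank = d.groupby(run_key, sort=False).cumcount()
    d = d[rank >= config.drop_first_k_trials]
    return (
        d.groupby(["condition", "repetition"])["rt_s"]
        .agg(mean_rt_s="mean", n="size")
        .reset_index()
    )
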