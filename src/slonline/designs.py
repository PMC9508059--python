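"""Constrained stimulus-sequence generation for serial reaction time (SRT)
statistical-learning experiments.

A run is a stream of briefly presented stimuli, each requiring a speeded
two-alternative categorization (abstract categories ``A``/``B``).  Hidden in
the stream are *information chunks*: associated stimulus pairs whose second
member always follows the first (within-pair transition probability 1), and
unpaired single stimuli that serve as a no-regularity control.  Condition
labels follow the field's convention: ``P1`` (first member of a pair,
anticipation marker), ``P2`` (second member, priming marker), ``S`` (single).

Three named presets are provided:

``exp1a``
    12 stimuli per run; four category-alternating pairs (A→B, B→A) plus four
    singles; 6 cycles × 12 trials = 72 trials; fixed 500 ms ITI; 8 runs.
    Because every pair alternates categories, the motor response alternates
    deterministically on P2 — the design that invites a motor-priming
    confound.
``exp1b``
    As ``exp1a`` but with balanced pair templates (A→B, B→A, A→A, B→B), which
    equalizes category transitions (~47.6 % repetition rate) and removes the
    motor confound.
``exp2``
    16 stimuli per run; balanced pairs plus eight singles; a warm-up of 10
    fully random cycles (160 trials) followed by 15 structured cycles (240
    trials); every pair is followed by at least one single; jittered
    500–1200 ms ITI; 2 runs.

Within every structured cycle each chunk appears exactly once in a random
order; orders are redrawn (rejection sampling) until the cycle-juncture and
pair→single constraints hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

CONDITION_P1 = "P1"
CONDITION_P2 = "P2"
CONDITION_S = "S"
CONDITION_RANDOM = "RANDOM"

PHASE_WARMUP = "warmup"
PHASE_STRUCTURED = "structured"

#: column order of the trial-table CSV dialect
TRIAL_COLUMNS = [
    "session_id",
    "subject_id",
    "run",
    "trial",
    "phase",
    "stimulus_id",
    "category",
    "condition",
    "chunk_id",
    "repetition",
    "iti_ms",
]

_REDRAW_BUDGET = 10_000


@dataclass(frozen=True)
class DesignSpec:
    """Full parameterization of one experiment variant.

    ``pair_templates`` are ordered category pairs; they are cycled to build
    ``n_pairs`` pairs (e.g. two templates and four pairs gives two pairs per
    template).  ``iti_ms`` is a ``(lo, hi)`` range in milliseconds; ``lo ==
    hi`` means a fixed intertrial interval, otherwise ITIs are drawn
    uniformly from the range.
    """

    name: str
    pair_templates: tuple[tuple[str, str], ...]
    n_pairs: int
    n_singles_per_category: int
    n_cycles: int
    warmup_cycles: int
    juncture_min_gap: int
    pair_followed_by_single: bool
    n_runs: int
    iti_ms: tuple[float, float]
    stimulus_duration_ms: float = 300.0
    categories: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if self.n_pairs < 0 or self.n_singles_per_category < 0:
            raise ConfigurationError("chunk counts must be non-negative")
        if self.n_cycles < 1 or self.n_runs < 1:
            raise ConfigurationError("n_cycles and n_runs must be >= 1")
        if self.juncture_min_gap < 0:
            raise ConfigurationError("juncture_min_gap must be >= 0")
        if len(self.categories) != 2:
            raise ConfigurationError("exactly two categories are supported")
        if self.iti_ms[1] < self.iti_ms[0] or self.iti_ms[0] < 0:
            raise ConfigurationError(f"invalid ITI range {self.iti_ms}")
        for tpl in self.pair_templates:
            if len(tpl) != 2 or any(c not in self.categories for c in tpl):
                raise ConfigurationError(f"bad pair template {tpl!r}")
        counts = self.category_counts()
        if len(set(counts.values())) != 1:
            raise ConfigurationError(
                f"category imbalance in spec {self.name!r}: {counts}"
            )

    # ------------------------------------------------------------------ sizes
    def pair_categories(self) -> list[tuple[str, str]]:
        """Categories of each pair, templates cycled to ``n_pairs``."""
        if self.n_pairs and not self.pair_templates:
            raise ConfigurationError("n_pairs > 0 but no pair templates")
        return [
            self.pair_templates[i % len(self.pair_templates)]
            for i in range(self.n_pairs)
        ]

    def category_counts(self) -> dict[str, int]:
        counts = {c: self.n_singles_per_category for c in self.categories}
        for a, b in self.pair_categories():
            counts[a] += 1
            counts[b] += 1
        return counts

    @property
    def n_singles(self) -> int:
        return self.n_singles_per_category * len(self.categories)

    @property
    def n_chunks(self) -> int:
        return self.n_pairs + self.n_singles

    @property
    def n_stimuli(self) -> int:
        return 2 * self.n_pairs + self.n_singles

    @property
    def trials_per_cycle(self) -> int:
        return self.n_stimuli

    @property
    def n_warmup_trials(self) -> int:
        return self.warmup_cycles * self.n_stimuli

    @property
    def n_structured_trials(self) -> int:
        return self.n_cycles * self.trials_per_cycle

    @property
    def n_trials_per_run(self) -> int:
        return self.n_warmup_trials + self.n_structured_trials


EXP1A = DesignSpec(
    name="exp1a",
    pair_templates=(("A", "B"), ("B", "A")),
    n_pairs=4,
    n_singles_per_category=2,
    n_cycles=6,
    warmup_cycles=0,
    juncture_min_gap=3,
    pair_followed_by_single=False,
    n_runs=8,
    iti_ms=(500.0, 500.0),
)

EXP1B = DesignSpec(
    name="exp1b",
    pair_templates=(("A", "B"), ("B", "A"), ("A", "A"), ("B", "B")),
    n_pairs=4,
    n_singles_per_category=2,
    n_cycles=6,
    warmup_cycles=0,
    juncture_min_gap=3,
    pair_followed_by_single=False,
    n_runs=8,
    iti_ms=(500.0, 500.0),
)

EXP2 = DesignSpec(
    name="exp2",
    pair_templates=(("A", "B"), ("B", "A"), ("A", "A"), ("B", "B")),
    n_pairs=4,
    n_singles_per_category=4,
    n_cycles=15,
    warmup_cycles=10,
    juncture_min_gap=3,
    pair_followed_by_single=True,
    n_runs=2,
    iti_ms=(500.0, 1200.0),
)

PRESETS = {"exp1a": EXP1A, "exp1b": EXP1B, "exp2": EXP2}


def get_preset(name: str) -> DesignSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown design preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Chunk:
    """One information chunk: an associated pair or a single stimulus."""

    chunk_id: str
    kind: str  # "pair" | "single"
    stimuli: tuple[str, ...]
    categories: tuple[str, ...]

    @property
    def conditions(self) -> tuple[str, ...]:
        if self.kind == "pair":
            return (CONDITION_P1, CONDITION_P2)
        return (CONDITION_S,)

    def __post_init__(self):
        if self.kind not in ("pair", "single"):
            raise ConfigurationError(f"bad chunk kind {self.kind!r}")
        expected = 2 if self.kind == "pair" else 1
        if len(self.stimuli) != expected or len(self.categories) != expected:
            raise ConfigurationError(
                f"chunk {self.chunk_id!r}: {self.kind} needs {expected} stimuli"
            )


@dataclass(frozen=True)
class Trial:
    """One presentation event.

    ``repetition`` is the 1-based count of structured-phase appearances of
    this trial's chunk ("presentation number"); warm-up trials carry the
    sentinel 0 and condition ``RANDOM``.
    """

    session_id: str
    subject_id: str
    run_index: int
    trial_index: int
    phase: str
    stimulus_id: str
    category: str
    condition: str
    chunk_id: str
    repetition: int
    iti_ms: float


def make_chunks(
    spec: DesignSpec, rng: np.random.Generator, id_prefix: str = "stim"
) -> list[Chunk]:
    """Build the chunk inventory with fresh stimulus ids randomly assigned.

    Ids are ``{id_prefix}{k:03d}``; randomization only permutes which id
    lands in which role, so distinct prefixes guarantee disjoint inventories
    (new stimuli for every run of a session).
    """
    counts = spec.category_counts()
    n_total = sum(counts.values())
    ids = [f"{id_prefix}{k:03d}" for k in range(n_total)]
    order = rng.permutation(n_total)
    pools: dict[str, list[str]] = {}
    at = 0
    for cat in spec.categories:
        pools[cat] = [ids[i] for i in order[at : at + counts[cat]]]
        at += counts[cat]

    chunks: list[Chunk] = []
    for p, (ca, cb) in enumerate(spec.pair_categories()):
        chunks.append(
            Chunk(
                chunk_id=f"pair{p}",
                kind="pair",
                stimuli=(pools[ca].pop(), pools[cb].pop()),
                categories=(ca, cb),
            )
        )
    s = 0
    for cat in spec.categories:
        for _ in range(spec.n_singles_per_category):
            chunks.append(
                Chunk(
                    chunk_id=f"single{s}",
                    kind="single",
                    stimuli=(pools[cat].pop(),),
                    categories=(cat,),
                )
            )
            s += 1
    return chunks


def _cycle_ok(
    order: Sequence[Chunk],
    prev_stimuli: Sequence[str] | None,
    prev_last_was_pair: bool,
    spec: DesignSpec,
) -> bool:
    """Check one candidate cycle order against the sequence constraints.

    The juncture constraint — a stimulus may recur only after at least
    ``juncture_min_gap`` *distinct* other stimuli — binds only across the
    cycle boundary because each stimulus appears exactly once per cycle.
    """
    if spec.pair_followed_by_single:
        if prev_last_was_pair and order[0].kind == "pair":
            return False
        for cur, nxt in zip(order, order[1:]):
            if cur.kind == "pair" and nxt.kind == "pair":
                return False
    if spec.juncture_min_gap > 0 and prev_stimuli is not None:
        new_stimuli = [s for ch in order for s in ch.stimuli]
        pos_prev = {s: i for i, s in enumerate(prev_stimuli)}
        for j, s in enumerate(new_stimuli):
            if j > spec.juncture_min_gap:
                break  # j distinct predecessors already guarantee the gap
            i = pos_prev.get(s)
            if i is None:
                continue
            between = set(prev_stimuli[i + 1 :])
            between.update(new_stimuli[:j])
            between.discard(s)
            if len(between) < spec.juncture_min_gap:
                return False
    return True


def _sample_cycle(
    chunks: list[Chunk],
    prev_stimuli: list[str] | None,
    prev_last_was_pair: bool,
    spec: DesignSpec,
    rng: np.random.Generator,
) -> list[Chunk]:
    n = len(chunks)
    for _ in range(_REDRAW_BUDGET):
        order = [chunks[i] for i in rng.permutation(n)]
        if _cycle_ok(order, prev_stimuli, prev_last_was_pair, spec):
            return order
    raise GenerationError(
        f"design {spec.name!r}: no valid cycle order within "
        f"{_REDRAW_BUDGET} redraws (juncture gap {spec.juncture_min_gap}, "
        f"pair_followed_by_single={spec.pair_followed_by_single})"
    )


def _draw_iti(spec: DesignSpec, rng: np.random.Generator) -> float:
    lo, hi = spec.iti_ms
    if hi == lo:
        return float(lo)
    return float(rng.uniform(lo, hi))


def generate_run(
    spec: DesignSpec,
    chunks: list[Chunk],
    rng: np.random.Generator,
    session_id: str = "sess0",
    subject_id: str = "sub000",
    run_index: int = 0,
) -> list[Trial]:
    """Generate one run: optional warm-up cycles, then structured cycles.

    Warm-up cycles are independent uniform permutations of all stimuli with
    no immediate repeat across cycle boundaries.  Structured cycles contain
    every chunk exactly once; orders are rejection-sampled until the
    juncture and (for designs that use it) pair→single constraints hold,
    including across the warm-up/structured boundary.
    """
    if len(chunks) != spec.n_chunks:
        raise ConfigurationError(
            f"inventory size {len(chunks)} != spec n_chunks {spec.n_chunks}"
        )
    all_stimuli = [s for ch in chunks for s in ch.stimuli]
    if len(set(all_stimuli)) != spec.n_stimuli:
        raise ConfigurationError("duplicate stimulus ids in chunk inventory")

    trials: list[Trial] = []
    t = 0
    stim_cat = {
        s: c for ch in chunks for s, c in zip(ch.stimuli, ch.categories)
    }

    prev_stimuli: list[str] | None = None
    for _ in range(spec.warmup_cycles):
        for _ in range(_REDRAW_BUDGET):
            perm = [all_stimuli[i] for i in rng.permutation(len(all_stimuli))]
            if prev_stimuli is None or perm[0] != prev_stimuli[-1]:
                break
        else:  # pragma: no cover - budget exhaustion is practically unreachable
            raise GenerationError("warm-up: no valid permutation within budget")
        for s in perm:
            trials.append(
                Trial(
                    session_id,
                    subject_id,
                    run_index,
                    t,
                    PHASE_WARMUP,
                    s,
                    stim_cat[s],
                    CONDITION_RANDOM,
                    "",
                    0,
                    _draw_iti(spec, rng),
                )
            )
            t += 1
        prev_stimuli = perm

    prev_last_was_pair = False
    for cycle in range(spec.n_cycles):
        order = _sample_cycle(chunks, prev_stimuli, prev_last_was_pair, spec, rng)
        cycle_stimuli: list[str] = []
        for ch in order:
            for s, cat, cond in zip(ch.stimuli, ch.categories, ch.conditions):
                trials.append(
                    Trial(
                        session_id,
                        subject_id,
                        run_index,
                        t,
                        PHASE_STRUCTURED,
                        s,
                        cat,
                        cond,
                        ch.chunk_id,
                        cycle + 1,
                        _draw_iti(spec, rng),
                    )
                )
                t += 1
                cycle_stimuli.append(s)
        prev_stimuli = cycle_stimuli
        prev_last_was_pair = order[-1].kind == "pair"
    return trials


def generate_session(
    spec: DesignSpec,
    subject_id: str,
    rng: np.random.Generator,
    session_id: str | None = None,
) -> list[list[Trial]]:
    """Generate ``spec.n_runs`` runs with disjoint stimulus-id sets."""
    session_id = session_id if session_id is not None else f"{subject_id}_sess"
    runs = []
    for r in range(spec.n_runs):
        chunks = make_chunks(spec, rng, id_prefix=f"{subject_id}_r{r}_s")
        runs.append(
            generate_run(
                spec,
                chunks,
                rng,
                session_id=session_id,
                subject_id=subject_id,
                run_index=r,
            )
        )
    return runs


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Flatten Trial records (or lists of them) into the schema DataFrame."""
    rows = []
    for item in trials:
        if isinstance(item, Trial):
            rows.append(item)
        else:
            rows.extend(item)
    return pd.DataFrame(
        {
            "session_id": [tr.session_id for tr in rows],
            "subject_id": [tr.subject_id for tr in rows],
            "run": [tr.run_index for tr in rows],
            "trial": [tr.trial_index for tr in rows],
            "phase": [tr.phase for tr in rows],
            "stimulus_id": [tr.stimulus_id for tr in rows],
            "category": [tr.category for tr in rows],
            "condition": [tr.condition for tr in rows],
            "chunk_id": [tr.chunk_id for tr in rows],
            "repetition": [tr.repetition for tr in rows],
            "iti_ms": [tr.iti_ms for tr in rows],
        },
        columns=TRIAL_COLUMNS,
    )


@dataclass(frozen=True)
class TransitionStats:
    """Empirical transition structure of structured-phase sequences.

    All probabilities are conditional on the current trial; "mean over
    successors" averages the empirical conditional probability over the
    eligible successor chunks (e.g. the seven *other* chunks for the
    generic case, or the eight singles after a pair in the larger design).
    """

    within_pair_prob: float
    other_case_prob: float          # specific other chunk follows, self excluded
    other_case_prob_incl_self: float  # same, averaged over all chunks incl. self
    p2_to_single_prob: float        # specific single follows a pair
    single_to_other_single_prob: float  # specific other single follows a single
    category_repetition_rate: float
    n_transitions: int


def empirical_transition_stats(frame: pd.DataFrame) -> TransitionStats:
    """Measure transition probabilities from generated structured trials.

    ``frame`` may pool many runs (and subjects); transitions are only
    counted within a run.  Chunk roles are aggregated by chunk label, which
    is shared across runs of the same design.
    """
    df = frame[frame["phase"] == PHASE_STRUCTURED]
    if df.empty:
        raise ConfigurationError("empirical_transition_stats: no structured trials")
    df = df.sort_values(["session_id", "subject_id", "run", "trial"], kind="stable")
    grp = [df[c] for c in ("session_id", "subject_id", "run")]
    same_run = pd.Series(True, index=df.index)
    for g in grp:
        same_run &= g.eq(g.shift(-1))

    nxt_chunk = df["chunk_id"].shift(-1)
    nxt_cond = df["condition"].shift(-1)
    nxt_cat = df["category"].shift(-1)

    # (i) within-pair transition probability
    p1 = (df["condition"] == CONDITION_P1) & same_run
    if p1.sum() == 0:
        within_pair = float("nan")
    else:
        hit = (nxt_chunk[p1] == df.loc[p1, "chunk_id"]) & (
            nxt_cond[p1] == CONDITION_P2
        )
        within_pair = float(hit.mean())

    # successor matrix over chunk-final trials
    is_final = df["condition"].isin((CONDITION_P2, CONDITION_S)) & same_run
    cur = df.loc[is_final, "chunk_id"]
    suc = nxt_chunk[is_final]
    counts = pd.crosstab(cur, suc)
    labels = sorted(set(df["chunk_id"].unique()))
    counts = counts.reindex(index=labels, columns=labels, fill_value=0)
    probs = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)

    singles = [c for c in labels if c.startswith("single")]
    pairs = [c for c in labels if c.startswith("pair")]

    def _mean_prob(from_labels, to_labels, exclude_self):
        vals = []
        for k in from_labels:
            for j in to_labels:
                if exclude_self and j == k:
                    continue
                vals.append(probs.loc[k, j])
        return float(np.nanmean(vals)) if vals else float("nan")

    other_case = _mean_prob(labels, labels, exclude_self=True)
    other_case_incl = _mean_prob(labels, labels, exclude_self=False)
    p2_to_single = _mean_prob(pairs, singles, exclude_self=True)
    single_to_single = _mean_prob(singles, singles, exclude_self=True)

    cat_rep = float((nxt_cat[same_run] == df.loc[same_run, "category"]).mean())

    return TransitionStats(
        within_pair_prob=within_pair,
        other_case_prob=other_case,
        other_case_prob_incl_self=other_case_incl,
        p2_to_single_prob=p2_to_single,
        single_to_other_single_prob=single_to_single,
        category_repetition_rate=cat_rep,
        n_transitions=int(same_run.sum()),
    )
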