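# Methods

This note documents the models, estimation choices and known limitations
behind `slonline`. It covers the sequence designs, the synthetic observer,
the exclusion cascade, the inference stack, and the Monte-Carlo problem
sizes used in the automated checks.

## Sequence designs

A run is a stream of 2AFC categorization trials over two abstract
categories `A`/`B` (mapping to concrete labels such as Large/Small or
Object/Animal is metadata). The stream is built from *information chunks*:
ordered stimulus pairs (conditions `P1`, `P2`) and unpaired singles (`S`).
In every structured cycle each chunk appears exactly once in random order,
so a chunk's repetition number equals the cycle number.

| preset | stimuli/run | pairs | singles | cycles | warm-up | runs | ITI (ms) |
|--------|------------|-------|---------|--------|---------|------|----------|
| exp1a  | 12 | 4, all category-alternating | 4 | 6 | — | 8 | fixed 500 |
| exp1b  | 12 | 4, balanced (2 alternating + 2 repeating) | 4 | 6 | — | 8 | fixed 500 |
| exp2   | 16 | 4, balanced | 8 | 15 | 10 random cycles (160 trials) | 2 | uniform 500–1200 |

Constraints, enforced by drawing each cycle's chunk order uniformly and
redrawing on violation (budget 10,000 redraws per cycle, exhaustion is an
explicit error):

- **Cycle juncture** — a stimulus may recur only after at least 3 distinct
  other stimuli. Within a cycle this holds automatically (each stimulus
  appears once); the check binds across cycle boundaries. We apply the same
  gap in all three presets: the warm-up design is described as sharing the
  fixed-sequence designs' regularity, and the gap also rules out immediate
  stimulus repeats and chunk self-succession everywhere.
- **Pair→single** (`exp2` only) — the chunk after any pair is a single,
  including across cycle boundaries.
- **Warm-up** — each warm-up cycle is an independent uniform permutation of
  all stimuli with no immediate repeat across cycle boundaries; the first
  structured cycle also respects the juncture gap against the last warm-up
  cycle.

Stimulus ids are fresh per run (a session never reuses an id), and fresh
ids are randomly assigned to chunk roles per run.

### Realized transition structure

`empirical_transition_stats` audits generated sequences. Within-pair
transitions are 1.0 by construction. Because chunk self-succession is
impossible, the mean probability that a *specific other* chunk follows a
chunk-final stimulus is exactly 1/7 ≈ 14.3 % in the 8-chunk designs, and
the mean probability that a specific single follows a pair is exactly
1/8 = 12.5 % in the warm-up design. The balanced designs' category-
repetition rate converges to ≈ 47.6 %.

One printed design value is *not* reproducible: a 9.1 % (= 1/11)
single→specific-other-single probability in the warm-up design. That
number treats the successor of a single as uniform over the 11 remaining
chunks, but the pair→single constraint forbids this: every pair's
predecessor must itself be a single, so exactly (8 − 4)/8 = 1/2 of
single-exits lead to singles *for any sampler honoring the constraint*,
giving ≈ 1/14 ≈ 7.1 % per specific other single (≈ 7.2 % with run-edge
effects). The package reports the honest empirical value.

## Synthetic observer

For subject *i*, picture *p*, condition *c*, chunk repetition *r*:

    RT = beta0 + b_i + (beta_rep + s_i)·ln r + b_p + beta_iti·(ITI − 500 ms)
         − prime_amp·f(r)·[c = P2] + anticip_amp·f(r)·[c = P1]
         − motor_amp·ln(1 + exposure)·[response category alternates]
         + nvar offset + N(0, sigma_resid²),  truncated below at 50 ms

with b_i ~ N(0, sd_subject_int²), s_i ~ N(0, sd_subject_slope²),
b_p ~ N(0, sd_picture²). Warm-up trials receive no repetition or condition
terms. Correctness is Bernoulli(1 − lapse), optionally condition-dependent.
NVAR offsets (classes 2–4 relative to 1) are derived from the generated
correctness stream, mirroring the analysis coding.

Defaults (the package's reference conditions): `beta0` 0.6 s,
`beta_rep` +0.001 s/ln-unit, `prime_amp` 0.005 s/ln-unit (so the P2 trend
is ≈ −0.004 s/ln-unit against a +0.001 control trend, the scale of the
published effect), `anticip_amp` 0 (no anticipation was detected),
`sd_subject_int` 0.08 s, `sd_subject_slope` 0.002, `sd_picture` 0.02 s,
`beta_iti` 2×10⁻⁵ s/ms, `sigma_resid` 0.1 s, `lapse_rate` 0.06, NVAR
offsets (0.02, 0.02, 0.04) s. The fixed mean slope `beta_rep` is needed to
place the control condition's trend at its nonzero published scale; the
ITI effect is parameterized against the 500 ms baseline so `beta0` stays
the grand mean under fixed-ITI designs.

The learning shape f(r) is ln r by default; a linear alternative (scaled to
match the logarithmic curve's endpoint effect) exists solely to exercise
the shape-discrimination machinery. The motor-confound accrual
g = ln(1 + trials seen in session) is a modeling stand-in — the confound is
known to grow across runs independent of the stimulus set, but no growth
law is published. `motor_amp` = 0.007 s reproduces a ≈ 0.019 s spurious
P2−S gap under the all-alternating design (alternation-rate difference
≈ 0.5 between P2 and the other conditions, mean accrual ≈ 5.7).

What the generator does *not* emulate: sequential RT autocorrelation beyond
NVAR offsets, fatigue/drift within runs, heavy-tailed or lognormal RT
distributions (residuals are truncated Gaussian, consistent with analyzing
raw RT with linear models), and human-like occasional low-accuracy runs
(lapses are i.i.d.). Passing tests therefore validate the pipeline's logic
and calibration on well-specified data, not robustness to every human
artifact. In particular the published "38 % of trials lost" in the
category-repeating reanalysis includes ~9 % whole-run accuracy exclusions
that i.i.d. lapses do not produce; the synthetic figure is ≈ 30 %.

## Exclusion cascade

Order: subject exclusion (session accuracy < 60 %) → run exclusion
(run accuracy < 80 %) → NVAR coding → fast trim (RT < 200 ms) → slow trim
(RT > mean + k·SD) → warm-up removal → first-presentation removal
(repetition 1 carries no learning signal). Thresholds are strict
inequalities ("under 80 %" excludes only below 80 %). k = 3 for the
fixed-sequence designs, k = 2 for the warm-up design.

The slow-trim reference population is each subject's correct structured
trials across the whole session (per-run and per-condition groupings are
available via `trim_grouping`); accuracies are computed before RT trims, so
run/subject exclusion does not depend on trimming. Incorrect trials are
retained with `rt_valid = False`: they keep accuracy denominators intact
but never enter mean RTs. Re-running the cascade on its own output is a
no-op: tables already carrying `nvar`/`rt_valid` are treated as coded and
trimmed, because recomputing either after row removal would corrupt codes
that must reflect the actual presentation stream.

Note a real cost of aggressive trimming: cutting at mean + 2 SD removes
≈ 2.3 % of *genuine* Gaussian upper-tail mass and does so asymmetrically
across conditions whose means have separated, which measurably attenuates
learning-trend contrasts on synthetic data. The package's calibration and
recovery checks therefore run under the 3 SD trim; the 2 SD setting remains
the default for warm-up-design analyses because with human data the
early-run variance it targets dominates this small censoring bias.

## Group inference (fixed-sequence designs)

Per-subject condition summaries: mean RT over correct, RT-valid structured
trials; accuracy as per-run proportion correct, medianed over runs. RM-
ANOVA uses the standard subject × condition decomposition
(df = (k−1), (k−1)(n−1); no sphericity correction, matching the published
analyses); pairwise comparisons are Tukey-Kramer studentized-range tests on
the RM error mean square, with paired Cohen's d. Accuracy uses Friedman
(χ², df = k−1) with pairwise Wilcoxon signed-rank z and rank-biserial
r = |z|/√n. Between-cohort comparisons take per-subject difference scores
(P1−P2, P2−S, P1−S), two-sample t for RT and Mann-Whitney U for accuracy,
Holm-Bonferroni within each measure. Degenerate inputs (identical
conditions) return F = 0 / χ² = 0 with p = 1 rather than 0/0.

## Trajectory inference (warm-up design)

REML mixed model `rt ~ ln(repetition)·condition + ITI` (condition reference
S, covariates centered) with subject intercept + slope on ln(repetition),
picture and NVAR variance components. Pictures are unique to each subject,
so the picture component is exactly nested in subject. The NVAR component
is likewise fit at the subject level: the estimation backend (statsmodels
MixedLM) groups all random effects by one factor, so a globally crossed
4-level intercept is not expressible; with only four levels and a shared
variance parameter the subject-level form is a close surrogate. Rows with
missing NVAR (each run's first trial) are dropped.

Type-III tests are Wald χ² on the fixed-effect covariance, labeled
`wald-chi2 (asymptotic z)` — Satterthwaite degrees of freedom are not
available in the backend, so calibration is demonstrated by simulation
instead (below). EMMs are the condition dummies at the covariate means;
per-condition trends are the implied ln(repetition) slopes; pairwise EMM
and trend contrasts are z tests with Tukey adjustment via the
studentized-range distribution (k = 3, df → ∞), with a Holm fallback.
Optimization tries L-BFGS first and falls back to Powell, which is robust
when a variance component sits on the boundary; non-convergence raises a
structured error advising the reduced model (`TrajectoryModelSpec.reduced()`
drops the picture/NVAR components) or dropping the random slope — the
standard reduction path when a maximal model cannot be estimated. The
reduced model is also the default inside Monte-Carlo loops for speed; it
leaves the trend-contrast estimator unbiased because subject intercepts
and slopes are shared across conditions.

Accuracy uses a binomial mixed model (subject and picture intercepts) fit
by mean-field variational Bayes — statsmodels has no maximum-likelihood
binomial GLMM — with Wald-type χ² from posterior standard deviations. The
result is labeled with this method: mean-field posterior SDs are
approximate (typically too small), so magnitude checks, not p-values, are
the reliable use of the null behavior. The ITI covariate enters in seconds
to keep the variational optimizer on a unit scale.

### Shape comparison (encompassing test)

Per subject × repetition, the mean S RT minus mean P2 RT is regressed on
repetition (model a) and on ln(repetition) (model b); each is F-tested
against the model containing both predictors. Verdict "log" when a is
rejected and b is not, "linear" in the mirror case, otherwise
"indeterminate"; a flat difference curve short-circuits to indeterminate.
Subject-level rows (n_subjects × n_repetitions) follow the published
degrees of freedom; the combined model's R² can never fall below either
nested model's (asserted on every call). Repetition and ln(repetition) are
highly collinear over 2–15 (r ≈ 0.96), so shape discrimination needs high
signal-to-noise: the package's discrimination checks use a 0.005 s/ln-unit
amplitude with 0.01 s cell noise over 83 × 14 cells, where the correct
verdict is returned in a clear majority of replicates.

## Monte-Carlo checks and problem sizes

All stochastic checks derive substreams from one master seed (counter-based
fan-out keyed on stage/subject/run, so growing a cohort never perturbs
existing subjects). Sizes were chosen for single-CPU runtimes:

- **Confound reproduction** — 200 cohorts of 33 subjects per design: the
  motor-only observer yields a significant Tukey P2-vs-S contrast in
  essentially all all-alternating cohorts, collapsing to the false-positive
  floor after category-repeating-trial exclusion and under the balanced
  design.
- **Type-I calibration** — 500 null-observer simulations each: RM-ANOVA and
  Friedman on 10-subject balanced-design cohorts; the LMM interaction Wald
  test on 10-subject single-run warm-up cohorts (reduced model, 3 SD trim).
- **Recovery** — 200 warm-up cohorts of 60 subjects at the published effect
  scale; the mean S−P2 trend-contrast estimate is compared to the
  generating 0.005 s/ln-unit. Shape discrimination: 300 replicates per
  generating shape.

## Known limitations

- Wald (not Satterthwaite) type-III tests: slightly liberal at very small
  subject counts; calibrated at the sizes used here.
- The binomial GLMM is variational; treat its significance tests as
  approximate.
- The observer's Gaussian residuals understate human RT skew; SD-trim
  percentages on synthetic data (~2 % at 2 SD) differ from published
  human percentages for this reason.
- The 9.1 % printed single→single transition probability is analytically
  unattainable under the pair→single constraint (see above); the generator
  reports ≈ 7.2 %.
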