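# Methods

## Task model

A session is three blocks of 100 two-alternative trials (short vs long
stimulus). Within each block the stimuli are equally frequent and 40
correct responses are scheduled for a 5p reward — 30 on the rich stimulus,
10 on the lean one. Two pseudo-randomness constraints hold within each
block: no more than 4 identical stimuli in a row and no more than 3
scheduled rewards on consecutive trials. Blocks are generated
independently, so the caps are not enforced across block boundaries; the
design is described per block and the first trial of a block starts fresh.

Schedule construction is deterministic given the seed. The stimulus order
is drawn by sequential sampling with an exact feasibility look-ahead (a
partial sequence is extendable iff the remaining counts satisfy
`r_same ≤ cap·(r_other+1) − trailing_run` and `r_other ≤ cap·(r_same+1)`),
so it never dead-ends; reward positions are drawn by rejection sampling
under the run cap with a large retry budget, after an analytic feasibility
check (`R ≤ cap·(T−R+1)`) rejects impossible configurations outright.

The reward-postponement rule: a reward scheduled on a trial answered
incorrectly joins a per-stimulus pending pool and is delivered on a later
correct trial of the same stimulus that is not itself scheduled for reward.
Scheduled rewards take precedence over pending ones; at most one reward is
delivered per trial; feedback never follows an incorrect response. Pending
rewards carry across block boundaries within a session (the rule refers
only to "a later" trial), and any still pending at session end are
reported, not forced. Postponement can in principle create more than three
*realized* consecutive reinforcements; the constraint is enforced on the
planned schedule, which is how the task is specified, and realized runs are
recoverable from the trial log.

Trials with reaction times outside [200, 3000] ms are removed before
scoring; the boundary values themselves are retained, because the removal
rule targets trials strictly faster than 200 ms or slower than 3000 ms.
Participants earning less than £5.00 of the £6.00 maximum are excluded
from analysis.

## Scoring

The signal category is the rich stimulus (hits = rich trials answered with
the rich response), so the criterion measures bias toward the reinforced
category; scoring against a fixed physical stimulus instead is available by
passing that label. Rates are edge-corrected log-linearly
(H = (hits+½)/(n+1)) on every block uniformly — chosen over 1/(2N)
clipping for continuity and estimator consistency — which keeps rates
strictly inside (0, 1) where the normal quantile is defined and leaves the
midpoint 0.5 fixed. The reported criterion is sign-reversed once at scoring
time, +½[z(H)+z(F)], so positive values mean more bias toward the rich
response; with the conventional c = −½[z(H)+z(F)] the sign would run
against the intuitive reading of "more reward responsiveness".

## Agent model

Participants are simulated by a drifting-criterion signal-detection
learner: the simplest generative mechanism that produces
reward-responsiveness differences without discriminability differences.
Stimulus means sit at ∓0.5 on a decision axis with Gaussian percept noise
of SD 1/d′, so `perceptual_sensitivity` *is* the observer's true d′
(default mean 1.7 ± 0.30 between participants, clipped at 0.2 — accuracy
around 80%). The agent answers "long" when the percept exceeds its
criterion (start 0); each delivered reward shifts the criterion by
`reward_learning_rate` toward the rewarded response. An optional
exponential decay of the criterion back to its start value models
forgetting and defaults to 0. Reaction times are lognormal
(median ≈ 600 ms, σ_log = 0.35) with 2% anticipatory (<200 ms) and 2%
lapse (>3000 ms) trials so the validity filter is exercised; about 4% of
trials are removed per session.

Negative learning rates (possible in the tails of the per-participant
distribution) simply drift the criterion away from rewarded responses;
they are retained rather than truncated to keep group means exactly at
their configured values.

## Cohorts and effect calibration

Genotypes are drawn i.i.d. from Hardy–Weinberg proportions (risk-allele
frequency 0.33 by default) or fixed to exact counts (the study preset uses
23/62/79 for AA/AG/GG at n = 164). Demographics (age 22.3 ± 4.4 years,
44% male, two sites at 79/21%) are generated independently of genotype, so
demographic null checks are true nulls. The rich stimulus alternates
across participants (counterbalancing). All randomness descends from one
`SeedSequence` hierarchy — cohort → participant → (schedule stream, agent
stream) — so any participant is individually reproducible and the schedule
and behavioral noise streams are independent.

Only the reward-learning rate depends on genotype. Group means are set by
inverting a shipped Monte-Carlo calibration table
(`data/effect_calibration.json`, regenerated by
`scripts/calibrate_effects.py`: 400 sessions per point on an 8-point
learning-rate grid spanning ±0.004–0.010). Over this range the scored mean
criterion responds linearly to the learning rate (slope ≈ 50 criterion
units per unit rate) with session-level noise SD ≈ 0.10. The AA group is
anchored at rate 0 (no reward responsiveness, matching the observation
that the homozygous risk group never departs from zero bias); the GG rate
follows from the AA-vs-GG target d via the fitted slope and the predicted
within-group SD √(s₀² + (b·σ_lr)²); the AG rate is then solved by fixed
point so that the dominant contrast (carriers pooled, at equal group
sizes) hits its target, accounting for the extra carrier variance induced
by the AA/AG mean split. Requested targets outside the calibrated range
raise a calibration error rather than extrapolating.

The within-group learning-rate SD (0.0028) makes stable individual
differences contribute about three times the criterion variance of
session-level sampling noise — a trait-like ratio — while keeping
per-participant rates inside the linear region. With these defaults the
total within-group SD of mean criterion is ≈ 0.165 and the GG group mean
≈ 0.11, so per-group one-sample t-tests reproduce the qualitative pattern
(GG strongly non-zero, AA null) at realistic sample sizes.

What the generator does *not* emulate: session-to-session learning carry-
over, fatigue or attention drift within blocks, genotype–demographic
correlations, response-time/accuracy coupling, and any neural mechanism
behind the learning-rate difference. Passing tests therefore validate the
pipeline and its statistical calibration, not any claim about real
participants.

## Statistics

- χ² tests (Hardy–Weinberg with df = 1 after estimating the allele
  frequency; r×c independence) use no continuity correction.
- One-way ANOVA reports partial η² = SSB/(SSB+SSW); a summary-statistics
  variant rebuilds SSW from (n−1)s² for checking published tables.
- The mixed ANOVA is the classical univariate split-plot decomposition
  (between-groups SS tested against subjects-within-groups; block and
  block×group against the block×subjects error), valid for unbalanced
  groups; it matches R's `aov` with an `Error(subject/block)` stratum and
  pingouin's implementation exactly on shared cases. No sphericity
  correction is applied by default; Greenhouse–Geisser df scaling is
  available as an option. With a covariate, the between-subjects stratum
  becomes an ANCOVA on subject means (model-comparison/Type-III group SS,
  df error N−g−1); a subject-constant covariate cancels from
  within-subject deviations, so the within stratum is unchanged.
- Degrees of freedom are always derived from the data supplied, never
  copied from published tables (whose df are not always internally
  consistent).
- t-tests are two-sided and pooled-variance; Cohen's d uses the pooled SD.
  Pairwise contrasts default to Bonferroni (p × m, capped at 1).
- Power uses the noncentral t: δ = d/√(1/n₁+1/n₂), rejection region from
  the central t at df = n₁+n₂−2; a normal approximation is provided and
  agrees within 0.01 for df ≥ 100. One-sided by default, matching how such
  power calculations are usually reported for directional genetic
  hypotheses.

## Numerical and testing choices

- Normal quantiles come from scipy; the test suite cross-checks d′ and
  criterion against an independent AS241 (Wichura) implementation to 1e-9
  on a 99-point rate grid.
- Earnings are rounded to pence; the inclusion rule is `earnings ≥ £5.00`.
- Degenerate inputs (zero variance, empty stimulus cells, monomorphic
  samples, missing design cells) raise typed errors rather than returning
  NaN.
- Frequentist calibration is verified by simulation: mixed-ANOVA
  between-effect type-I error over 2000 null replicates at 30 subjects per
  group, and KS uniformity of null p-values for χ², one-way F and
  one-sample t at 2000 replicates each. Effect-size calibration is checked
  at 500 participants per genotype group; parameter recovery
  (criterion monotone in learning rate) at 200 sessions per rate. These
  problem sizes keep each check's Monte-Carlo error well below the
  tolerance it asserts.

## Known limitations

- Absolute criterion levels are a property of the agent model, not of any
  human dataset; only signs, orderings and standardized effects are
  meaningful points of comparison.
- The calibration table is specific to the default schedule and agent
  defaults; changing either requires regenerating it.
- The mixed ANCOVA adjusts the between-subjects stratum only; covariate ×
  block interactions are out of scope.
- Realized reinforcement runs after postponement are recorded but not
  constrained (see Task model).
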