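# Methods

## The task and the generative model

Each trial of the 2AFC force-discrimination task presents a 2 N *test* force
followed (800–1200 ms later) by a *comparison* force drawn from seven levels
(1, 1.5, 1.75, 2, 2.25, 2.5, 3 N); the observer reports which felt stronger.
The synthetic observer is logistic in the measured comparison magnitude `x`:

    P(report comparison stronger) = λ/2 + (1 − λ) · σ(β₁(x − PSE)),

with `β₁ = ln 3 / JND`, so the curve passes through 0.5 at the PSE and
through 0.75 / 0.25 at PSE ± JND by construction. The fitted model has no
lapse term (λ); the simulator supports λ ∈ [0, 0.5) (default 0) purely as a
robustness stressor for the lapse-free fit. Measured forces are the nominal
forces plus Gaussian jitter (sd 0.01 N, truncated at zero) representing
motor/sensor tolerance; the fitted `x` is the measured force binned back to
the nearest nominal level (ties at exact midpoints break toward the lower
level, and out-of-range values clamp to the extreme levels).

## Experiment presets

Three presets reproduce the trial structure of the paradigm's designs:

| preset | conditions | trials/participant |
|---|---|---|
| exp1 | baseline, contact, no-contact — blocked, 70 each | 210 |
| exp2 | as exp1 + NOGO trials intermixed at 50% in the contact and no-contact blocks | 350 |
| exp3 | 80% contact / 20% no-contact intermixed (224 + 56) + 56 baseline | 336 |

Every condition presents each of the seven comparison levels equally often in
randomized order. Block order counterbalancing is recorded as a label only;
no order effects are modelled.

## Population model

Between-participant heterogeneity in PSE is decomposed into a shared
participant offset (Gaussian, default sd 0.13 N, common to all conditions)
plus an independent condition-specific deviation (default sd 0.05 N). The
shared offset encodes the stable individual perceptual scale that a
within-subject design exploits; with 70 trials per condition these defaults
put paired effect sizes for a 0.2 N shift around d ≈ 1.2, the magnitude this
class of experiment reports. JNDs are log-Gaussian across participants
(moment-matched to mean 0.4 N, sd 0.1 N), which keeps every draw positive.
Default condition means place a 0.2 N contact attenuation, a 0.13 N
no-contact attenuation in the expectation-of-contact design (exp3) only, and
0.06–0.09 N suppression on NOGO (movement-inhibition) trials. These
population values are simulation defaults chosen to be directionally and
dimensionally realistic; they are not estimates from any real cohort.

Kinematics are summary scalars per trial, not trajectories: vertical endpoint
offset (mm) and test-force lead time relative to the movement endpoint (ms),
drawn Gaussian around condition-specific means (e.g. the contact endpoint
2.32 mm closer and the no-contact force leading by 24 ms in the exp1
profile). The intrinsic contact-trigger delay (36 ms) is carried as a
constant. NOGO trials record a small movement "twitch" magnitude.

## Trial exclusion

A trial is excluded iff (in this fixed precedence order, each trial counted
once under the first failing rule): missing response; measured test force
outside the *open* interval (1.85, 2.15) N; test force not triggered by the
movement; movement > 10 mm on a NOGO trial; force delivered after the
vertical movement endpoint; contact with the distance sensor (active only in
the retracting-platform design, exp3). The ledger reports per-reason and
per-participant counts and the rounded exclusion percentage, which always
recomputes exactly from the counts. Binning to nominal levels happens after
exclusion, on surviving trials only — the ordering is not dictated by the
procedure itself, and exclusion-first avoids binning invalid trials.

## Psychometric fitting

Maximum likelihood for the binomial logit GLM by iteratively reweighted
least squares (Newton) with step-halving, starting from (0, 0), converging
on gradient norm < 1e−8 within 100 iterations. Trials are aggregated to
per-level counts first; trial-level and aggregated fitting are ML-equivalent
and the test suite asserts rather than assumes this. Because the
canonical-link likelihood is concave, non-convergence implies complete or
quasi-complete separation or degenerate data, never a local optimum:
separation is detected up front (all observed per-level proportions in
{0, 1} and monotone, including the all-identical-responses case) and via a
divergence guard (|β| > 50), and flagged instead of returning divergent
estimates. Derived measures (PSE = −β₀/β₁, JND = ln 3/β₁, McFadden's
R² = 1 − ℓ_model/ℓ_null) are refused for separated, non-converged or
non-positive-slope fits. The JND uses the natural logarithm — the only base
consistent with the logit link's 75% point.

Participants with a degenerate fit in any condition are dropped listwise
from the paired contrasts and recorded in the results bundle.

## Statistical battery

- **Gate:** Shapiro–Wilk on the paired differences (scipy's Royston
  implementation); Wilcoxon iff p < α (default 0.05), else paired *t*.
- **Paired t:** t = m/(s/√n), df = n−1, Cohen's d = m/s, t-based CI95 on the
  mean difference. All-zero differences are reported as the degenerate
  t = 0, p = 1 result; constant nonzero differences (infinite t) raise.
- **Wilcoxon signed-rank:** zeros dropped, average ranks for ties,
  W = positive-rank sum. The two-tailed p is exact — the null distribution
  of W is built by dynamic programming over sign assignments on doubled
  ranks, identical to full 2ⁿ enumeration — for n ≤ 25, else a tie- and
  continuity-corrected normal approximation. Effect size is the matched
  rank-biserial r = (T⁺−T⁻)/(T⁺+T⁻); the CI95 is the Hodges–Lehmann
  interval from ordered Walsh averages trimmed at the exact signed-rank
  critical value (cross-checked against R's `wilcox.test(conf.int=TRUE)`).
- **Bayes factors:** the JZS one-sample BF with a Cauchy(0, 0.707) prior on
  standardised effect size, integrated by adaptive quadrature (relative
  tolerance 1e−8); BF₀₁ = 1/BF₁₀, with conventional anecdotal/moderate/
  strong labels. BF₀₁ is attached to non-significant contrasts only (a flag
  forces computation everywhere). For Wilcoxon-gated contrasts the BF is the
  same JZS t-test BF on the differences — an interpretation choice, not a
  Bayesian rank test, so published Bayes factors computed with other
  variants need not match exactly. An independent Monte-Carlo route
  (averaging normal densities over joint draws of the prior effect size and
  the χ² variance term) validates the quadrature in the test suite.
- **ANOVA:** one-way between-subjects decomposition; partial
  η² = SS_b/(SS_b+SS_w); Levene (mean-centred) attached, flagged undefined
  when a group is constant; post hocs are pooled-variance independent
  t-tests (df = n₁+n₂−2) with Bonferroni multiplication capped at 1.

Planned contrast sets per preset: exp1/exp3 compare contact, no-contact and
baseline pairwise; exp2 adds the four NOGO contrasts against baseline and
their GO/NOGO counterparts.

## Reproducibility and numerical choices

All simulation randomness flows through integer seeds via
`numpy.random.SeedSequence` spawning (one stream for population draws, one
per participant), so identical (config, seed) reproduce trial tables
bit-for-bit and byte-identical JSON outputs (sorted keys, no timestamps).
Anomaly injection iterates anomaly types in a fixed order with its own seed
and returns exact injection counts. Problem sizes used by the test suite and
the acceptance script — 10,003-trial recovery fits over 20 seeds, 10,000
replicates for type-I calibration, 10⁷ Monte-Carlo draws per Bayes-factor
grid point, 200 simulated cohorts for the end-to-end pattern — were chosen
as the smallest sizes at which the Monte-Carlo error of each check is well
below the band it asserts.

## What the simulator does and does not emulate

It emulates: the logistic decision rule, the seven-level design and trial
counts of all three experiments (including the 50% NOGO intermixing and the
80/20 contact mix), force-measurement jitter, per-participant heterogeneity
with realistic within-subject correlation, scalar kinematic summaries, and
every anomaly class that the exclusion rules act on. It does not emulate:
sequential/order effects, learning or fatigue, response times, full movement
trajectories, auditory cueing, or hardware electronics. Passing tests
therefore demonstrate that the analysis chain is correct and well calibrated
under the stated generative assumptions — not that those assumptions exhaust
the structure of real data.

## Known limitations

- The exact Wilcoxon p uses the tie-aware sign-assignment distribution;
  for very large n with heavy ties the normal approximation is used instead.
- The Hodges–Lehmann CI is one convention among several for a
  signed-rank-consistent interval; published intervals may use others.
- The fitted model has no lapse parameter; heavily lapsing observers bias
  JND upward (the simulator's lapse knob exists to probe exactly this).
- Bayes factors for non-normal contrasts reuse the t-statistic BF, which is
  an approximation whose published counterparts vary by software variant.
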