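# Methods

## The task and its synthetic emulation

The simulator (`salsup.synthetic`) reproduces the structure of an
additional-singleton session with an imbalanced distractor distribution:

- **Search schedule.** 5 blocks × 144 search trials. Targets are exactly
  balanced (18 per block at each of 8 ring locations, indexed 0–7
  counterclockwise with 0 = leftmost and 4 = rightmost horizontal-midline
  position). A distractor is present on a `presence_rate` fraction of trials
  (default 0.88); among present distractors an `hp_share` fraction (default
  0.50) sits at the fixed high-probability (HP) location (0 or 4,
  counterbalanced across simulated participants), the rest uniform over the
  other seven locations, never coinciding with the target. Fractional
  per-block counts are resolved by randomized rounding, so the configured
  rates hold exactly in expectation and to ±1 trial per block. The task
  description these defaults emulate states both an 88% presence rate and 56
  HP trials per block (which would imply 77.8% presence); the two cannot both
  hold in a 144-trial block, so both knobs are explicit configuration with
  the defaults above.
- **Probe trials.** After every search trial a brightness-judgment probe is
  inserted with probability 0.40 (~288 probes per session). One side shows
  the fixed standard color (spectrum position 187 of 0–509; 100 for the
  grayscale profile) and the other side shows its staircase's current value.
- **Search RTs.** Distractor-absent trials draw from the baseline
  ex-Gaussian; distractor-present trials first draw a capture event with the
  condition's probability (`p_capture_hp` = 0.44, `p_capture_lp` = 0.70 by
  default) and then draw from the capture or baseline curve. Default curves:
  baseline (K = 1.2, loc = 640 ms, scale = 72 ms; median 713.7 ms) and
  capture (K = 1.0, loc = 850 ms, scale = 90 ms; median 928.8 ms), i.e. a
  214.9 ms median capture cost — the study-scale quantities the estimators
  are validated against. Accuracy is Bernoulli (default 0.928). RT draws at
  or below zero are resampled, keeping densities proper.
- **Randomness.** Each (seed, participant) pair spawns independent
  substreams for search RTs, probe choices, staircase initialisation and
  standard-side draws, so changing the probe schedule can never perturb the
  search RT sequence, and a fixed seed reproduces every output table byte
  for byte.

### The observer's perceptual bias and sign conventions

The observer perceives a probe of physical value *v* at the HP side as
*v + s*, where *s* = `true_pse_shift` (default −9 degrees; negative =
perceived dimmer). Choices follow a lapse-mixed logistic on the subjective
brightness difference (slope 0.05 /degree, lapse 0.02), mirrored for the
darker-judgment task. Two consequences, both matching the study's headline
signs:

- each side's staircase converges to the value whose *subjective* brightness
  matches the standard — HP at 187 − s, LP at 187 + s — so the block-end
  difference LP − HP converges to 2s (−18 by default);
- the fitted psychometric midpoint on the combined-salience axis
  (hp − lp) sits at −s, and the **reported PSE** follows the suppression
  convention *negative = HP probes must be physically brighter to appear
  equal*, i.e. reported PSE = −midpoint = s (−9 by default). This reporting
  convention is applied uniformly to both task polarities (the darker task
  traces the mirrored curve around the same midpoint), so group tests pool
  them directly.

## Staircase (`salsup.staircase`)

A simplified-PEST track per side: start at 28 or 350 (uniform), step 64
degrees, range [0, 509]. On each probe the tested (non-standard) side's
value moves one step toward the subjective match — under the brighter task,
down if the staircased patch was chosen, up otherwise; mirrored for the
darker task. Response-side alternations are counted globally across the two
tracks; on the third consecutive alternation the tested track's step halves
(floor 1 degree) and the counter resets. Halving is restricted to the tested
track so per-side steps stay well defined. At block boundaries both tracks
restart at the previous ending value ±96 (random sign, clamped to the
spectrum) with a full 64-degree step. A `literal_update_rule` flag preserves
the divergent update the task description prints (chosen → brighter), for
audit; the default is the convergent reading, since homing in on the 50%
point is the staircase's stated purpose. Convergence is validated by a
threshold-observer sweep: for every threshold in [40, 470] the block-end
value lies within one terminal step, using one block's probe budget
(58 = 0.4 × 144 probes, all on the tested track since the oracle drives a
single side).

## Psychometrics (`salsup.psychometrics`)

Combined salience = hp_value − lp_value (degrees). Trials are stably sorted
by (score, input position) and split into 8 contiguous equal-count bins
(remainder to the lowest-score bins — deterministic, reproducible under
ties); each bin is labelled by its mean score and carries the proportion of
HP choices. A two-parameter logistic 1/(1 + exp(−slope·(x − midpoint))) is
least-squares fitted to the bin points, initialized at midpoint 0 and slope
+0.01 (brighter) or −0.01 (darker). No lapse/guess asymptotes are fitted —
lapses live only in the synthetic observer. Fits with degenerate slope
(|slope| < 1e−6, flat choice data) or runaway midpoint are flagged
`converged=False` and excluded from group tests. Group location tests use a
one-sample t-test with Cohen's d when Shapiro–Wilk does not reject normality
(α = .05), otherwise Wilcoxon signed-rank with the matched-pairs
rank-biserial correlation; the all-identical-zero edge case returns a null
statistic, any other zero-variance input is a degeneracy error.

## Preprocessing (`salsup.preprocess`)

Filter chain for RT analyses, in order: RT window 300–2000 ms ("less
than"/"longer than" read strictly, so the bounds themselves are kept);
per-participant ±2.5 SD trim with mean/SD computed once on the post-window
data (single pass — re-application would trim further, which is why the
chain applies it exactly once; incorrect trials are still present at this
point, matching the listed order of the cohort percentages); removal of
incorrect trials (skipped for accuracy analyses); role-specific location
repetition removal (a trial is a repetition only when the *adjacent original
presentation index* survives in the table and carries the same location —
absent-after-absent never counts); horizontal-midline restriction (locations
0 and 4; distractor-absent trials are retained in the distractor role as the
baseline set). Target analyses restrict to distractor-absent trials with
horizontal targets and use target-repetition removal. Condition labels:
absent / HP / LP plus the circular gradient distance 0–4 from the HP
location. Every application is recorded in a `FilterReport` whose counts
reconcile exactly.

Participant-level rules: group-accuracy ±2.5 SD; screen-test mismatch
strictly above 30 degrees; probe-error rule. "Wrong" has no objective
definition near subjective equality, so by default a probe response counts
as wrong only when the physical difference exceeds 64 degrees (one initial
step — decisively supra-threshold) and the polarity-inappropriate side was
chosen; the monochrome profiles drop wrong rates above 45%, the
colored-search profile drops probe accuracy below 55%. Participants missing
a screen-test record are dropped by default (the cohort procedure replaced
them), configurable.

## RT mixture modeling (`salsup.mixture`)

The ex-Gaussian density is computed in log space throughout;
where the erfc factor underflows, `erfcx` supplies
log erfc(t) = log erfcx(t) − t², so the log-density is finite for any finite
input (validated against a brute-force Gaussian⊗exponential quadrature to
1e−8 and against an independent library implementation of the same
parameterization). Medians are found by Brent root-finding on the CDF to
±0.01 ms.

The baseline curve is fitted to no-distractor RTs by maximum likelihood with
a moment-based start (tau from the sample skewness) and seeded multi-start
Nelder–Mead; log-normal, Weibull, chi-squared and inverse-gamma alternatives
are fitted alongside and ranked by BIC (all five are 3-parameter fits, so
the ranking reduces to likelihood). On ex-Gaussian data the ex-Gaussian wins
essentially always; on log-normal data the log-normal wins a majority, with
occasional wins by its close siblings (inverse-gamma, chi-squared) — an
intrinsic similarity, not an estimator defect.

Mixture fits hold the baseline fixed and optimize the capture curve(s) and
probability(ies) by L-BFGS-B on transformed parameters (log K, log scale,
capture probability through a scaled logistic pinned to [0.2, 0.8];
probabilities within 1e−3 of a bound are flagged). Sixteen seeded restarts
are run with a deterministic early stop once four consecutive restarts fail
to improve the incumbent optimum. `compare_models` ties the nested fits
together: disengagement is warm-started from the capture optimum, combined
from both restricted optima (guaranteeing the likelihood nesting
combined ≥ capture, disengagement), and disengagement is refined once more
from the combined optimum projected onto a shared capture probability —
without that refinement the 7-parameter disengagement fit can stall in local
optima and lose model-recovery comparisons it should win.

Two fit objectives are exposed. The default is trial-level maximum
likelihood (AIC = 2k − 2lnL, BIC = k·ln n − 2lnL with n = trials). The
alternative is least squares on 50-bin normalized RT histograms over
[300, 2000] ms per condition, with the Gaussian-error log-likelihood
−(n/2)(log 2πσ̂² + 1), σ̂² = SSE/n and n = 100 bins; this convention yields
negative criteria of the magnitude the study prints, but printed criterion
values are treated as convention-dependent and are not reproduction targets
— capture odds and curve medians are. Per-participant mode refits each
participant's own baseline from their no-distractor trials (their
no-capture behavior is their own), then compares models per participant
with a Greenhouse–Geisser-corrected repeated-measures ANOVA and matched
Wilcoxon pairwise tests with rank-biserial effect sizes.

## Pipeline (`salsup.pipeline`)

Stages run in order (simulate/load → participant exclusions → preprocess →
behavioral contrasts → staircase and PSE analyses → mixture comparison) and
each writes a plain-text artifact; the final report is sorted-key JSON
reproducible byte for byte from (config, seed) — the output directory is
deliberately excluded from the report's identity. Behavioral contrasts use
the rank-based fallback policy above; the gradient omnibus is GG-corrected
and gradient pairwise tests are Holm-corrected (the study reports pairwise
tables without naming a correction). Experiment profiles (`exp1a`, `exp1b`,
`exp2`) set probe polarity, color set, standard value, the probe-exclusion
style and the one-tailed group test for the colored-search profile.

## Validation studies and problem sizes

`salsup.validation` packages the simulation studies the acceptance checks
run: density accuracy (1,000 random points vs quadrature), capture-model
recovery (20 replicates × 8,000 trials/condition; recovered odds within
±0.03 and medians within ±10 ms of the generating truth), BIC model
recovery (20 + 20 datasets at 2,000 trials/condition, ≥90% correct in each
direction), the staircase threshold sweep and 100-subject shift study
(LP − HP within ±4 of −18), PSE recovery (50 subjects, ±3 of −9) and group
power (30 cohorts of 90 subjects). These sizes complete in a few minutes on
one CPU while keeping Monte-Carlo error well inside the stated tolerances.

## What passing tests do and do not show

The simulator generates exactly the structure the estimators assume:
independent trials, stationary capture probabilities, a logistic probe
chooser with constant lapse, and no drift, fatigue, sequential dependencies
(beyond the location repetitions the filters remove), response bias toward a
screen side, or between-participant heterogeneity unless configured.
Recovery on synthetic data therefore demonstrates estimator correctness and
calibration under the study conditions — not that real cohorts satisfy those
assumptions. Reproducing the deposited study estimates requires the external
data (see the README's deposit reference) through the CSV adapter; the
reproduction test states the expected file layout and remains red without
the files. Known limitations: no Bayesian/hierarchical mixture estimation,
no eye-movement or drift-diffusion modeling, no probe-RT modeling, and the
printed-criterion conventions noted above.
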