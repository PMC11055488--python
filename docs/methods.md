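# Methods

`effortbench` simulates and analyzes two behavioral listening-effort tests
for cochlear-implant (CI) users — a sentence verification test (SVT) and a
sentence-final word identification and recall test (SWIRT) — administered in
noise at two signal-to-noise ratios placed relative to each listener's own
50% speech reception threshold (SRT50 + 4 dB and SRT50 + 8 dB), in a test
and a retest session. This note documents the generative model, the
estimation machinery, the numerical choices, and what the synthetic data do
and do not establish about real measurements.

## Virtual listeners

Each listener carries a four-parameter logistic psychometric function for
word recognition in noise,

    p(snr) = g + (p_max − g) / (1 + A · exp(−β (snr − SRT50))),

re-anchored through `A = (p_max − g)/(0.5 − g) − 1` so that
`p(SRT50) = 0.5` exactly. Population defaults: SRT50 ~ Normal(3.1, 2.9²) dB,
growth β = 0.5 /dB, guess rate g = 0, asymptote p_max ~ Uniform(0.88, 0.99).
The CI literature gives no single printed slope for this population; β and
the p_max range are assumptions chosen so that the intelligibility
difference between the two test conditions, p(SRT50+8) − p(SRT50+4), falls
in the 0.04–0.10 band expected in the flattening region of CI psychometric
curves. A "word score in quiet" covariate is generated as a binomial draw
at the asymptote over a 78-word training list.

## Trial generation

**SVT.** Thirty sentences per condition (15 true, 15 false). Categorization
is two-stage: with probability given by the psychometric function (plus a
per-item difficulty offset, SD 1 dB) the sentence is understood and answered
correctly up to a lapse rate; otherwise the listener guesses, with a bias
toward answering "false" — this asymmetric guessing reproduces the
observation that false sentences are categorized correctly more often than
true ones. Shifted reaction times (seconds from the earliest countable
response) are Gamma distributed with constant shape (k = 4) and a log-mean
carrying condition, session (learning), condition-order, correctness and
truth-type terms plus participant, item and per-session random offsets.
Misses arise mechanistically: a drawn response later than 3.0 s after
sentence end is recorded as missing, which couples the ~2.2% miss rate to
the RT distribution rather than to an independent coin flip.

**SWIRT.** Five lists per condition; list length is 5 sentences unless the
listener recalled all 5 training words (then 7, to avoid ceiling). Final-word
repetition is Bernoulli at the psychometric function evaluated at the
condition SNR minus a final-word difficulty shift (0.72 dB, plus participant
and word offsets) — repetition inherits the condition effect from the
psychometric curve. End-of-list recall is Bernoulli on a logit scale with
list-position intercepts (first/middle/last), condition, session, word-type,
list and participant terms. A misheard final word whose substituted token is
reproduced at recall counts as correct recall, so recall success is modelled
independently of repetition success.

**Randomness.** Every draw runs on a named substream spawned from
`(seed, participant, purpose, session, condition)`, so trial tables are
bit-reproducible and adding participants never perturbs existing ones.
Item/list property tables are drawn once per configuration seed and shared
by the whole cohort, mimicking fixed test materials.

## Calibration of the defaults

The free generative parameters were fixed once by stochastic root-finding:
simulate a large cohort, compare its group descriptives to their targets,
nudge the responsible parameter, iterate — one loop around
`simulate_experiment`, with final constants confirmed by multi-seed
replication. Calibration targets
and the values the defaults reproduce at large n: miss rate 2.2%; SVT
accuracy 93.1% (false) / 86.8% (true); recall by position 92.2 / 64.4 /
57.0% (last/first/middle); per-participant condition differences of 11.6 pp
(repetition) and 3.8 pp (recall); between-session differences of 1.0 pp
(repetition) and 2.7 pp (recall). Because the item/list tables are shared
across a cohort, cohort-level replicates vary by ~0.4–0.8 pp SD in these
descriptives even at many hundreds of participants; the final constants were
therefore set from multi-seed dose-response runs, and the acceptance script
pools several independently seeded cohorts.

What the simulator does *not* emulate: real CI heterogeneity in psychometric
slope, attention lapses correlated over time, within-session (order)
learning beyond a constant offset, item-content effects beyond random
offsets, and any acoustic detail. Passing calibration tests shows the
analysis pipeline behaves correctly on data with the assumed structure, not
that real data have that structure.

## Adaptive SRT50 procedure

Sentence 1 is presented at +2 dB SNR; after each sentence the SNR moves by
`4 · (0.5 − word_score)` dB (word score on the proportion scale, so steps
are bounded in ±2 dB); 26 sentences are presented, a 27th SNR is computed
but not presented, and the SRT50 estimate is the mean of SNRs 5–27
(1-based), discarding the staircase burn-in. No SNR rounding or clipping is
applied. Against a symmetric logistic listener the procedure is nearly
unbiased: the psychometric function evaluated at the estimate averages 50%
correct to within Monte-Carlo error.

## Preprocessing

* Validity: an SVT response counts iff it falls in the inclusive window
  [−0.8 s, +3.0 s] around sentence end; "between" is read inclusively, the
  permissive interpretation. Invalid trials are retained with a missing
  outcome — no step in the module deletes rows.
* Shift: analysis RTs are `raw + 0.8 s`, making the support strictly
  positive for the Gamma family (0 s = earliest countable response).
* Item/list outliers: a pooled distribution is fitted to all trials of the
  most difficult condition (SRT50 + 4 dB) — binomial for binary outcomes,
  Gamma (MLE, location 0) for RTs — and each unit's mean is referred to its
  exact sampling distribution under the pooled fit (binomial tail for
  counts; Gamma(n·k, θ/n) for a mean of n draws). Units in the two-sided 1%
  tail are flagged. The two-sided reading makes the detector symmetric and
  conservative: under its own null the flag rate is at most 1%.
* Learning correction (SVT RT): per-participant session means, collapsed
  across conditions and order, give a least-squares line
  `retest = a + b·test`; each participant's correction
  `test_mean − (a + b·test_mean)` is added to their retest trials. The
  corrected retest data sit at the test session's expected level; the
  correction is idempotent and preserves the grand mean. Corrected retest
  RTs can rarely become nonpositive; such rows are excluded from Gamma
  model input (family support).

## GLMMs

Four models mirror the four study variables: Gamma log-link for shifted RT;
binomial logit for answer, repetition, and recall. Random effects are
crossed (participant × item/list), specified in a small formula dialect
(`y ~ a + b + (1 + a | group)`).

Estimation maximizes the Laplace approximation to the integrated
likelihood. Inner loop: penalized IRLS jointly over fixed effects and
random-effect modes, with random effects parametrized as `b = s·u` (columns
of Z scaled by the block SD, unit-normal penalty on u), which keeps the
working system well-conditioned as variances shrink to zero and makes the
zero-variance limit exactly the ordinary GLM. Outer loop: Nelder–Mead over
the log SDs of the random-effect blocks (plus the log Gamma shape), with
warm-started inner solutions. Design choices:

* Random-effect blocks are independent (diagonal covariance): each grouping
  factor contributes an intercept block and one block per slope column, each
  with its own variance and no intercept–slope correlation. At this study's
  group counts (18 participants, tens of items) correlation parameters are
  weakly identified; the diagonal form is the robust default.
* Inference on coefficients is Wald-z (no finite-sample df theory exists
  for GLMMs); 95% CIs are ±1.96 SE from the Schur complement of the joint
  penalized Hessian.
* AIC = 2k − 2·logLik with k = fixed coefficients + variance parameters
  (+1 for the Gamma shape). Backward selection removes one fixed term or
  random term per step (interactions before their main effects; a slope's
  variable stays fixed while the slope exists), keeps the reduction with the
  lowest AIC, and stops when nothing improves; ties within 1e−9 prefer
  fewer parameters. If the full model fails to converge, random slopes are
  stripped first, item/list groups before participant.
* Added interactions are judged by a likelihood-ratio χ² between nested
  fits (df = parameter difference), kept at p < 0.05.
* Standardization: continuous predictors are z-scored and the model refit;
  binary dummies and the response are untouched (a logit/log response
  cannot be z-scored). A standardized coefficient is therefore the
  link-scale effect of a one-SD predictor change. The original reporting
  toolchain's convention for Gamma responses is not documented anywhere we
  could verify; predictors-only scaling is this package's assumption.
* R² (marginal/conditional) uses the link-scale variance decomposition with
  family residual variance π²/3 (logit) or ψ₁(shape) (trigamma, Gamma-log);
  the random-effect contribution is the row-wise mean of diag(ZΣZ′).
* Overdispersion: Pearson χ² over residual df (n − k), flagged above 1.5.

Validation: the Laplace log-likelihood matches a 50-node adaptive
Gauss–Hermite oracle to <0.05 on moderate-variance single-intercept
binomial fixtures (the gap grows with the random-effect SD and shrinks with
cluster size, as theory predicts — at σ̂≈1.3 with 10-observation clusters it
reaches ~0.2); fits agree with R's lme4/glmmTMB on fixtures to ~0.02 in
coefficients (the small binomial discrepancy reflects profiled-β vs
jointly-optimized-β Laplace variants); Wald CIs attain ≥90% empirical
coverage in simulate-and-refit studies. Like any Laplace estimator, Bernoulli
fits with small clusters attenuate variance components and coefficients by a
few percent.

## Intra-individual detection

For each measure, per-participant mean test−retest differences (RTs after
learning correction) are fitted with a maximum-likelihood normal (divisor
n), and the significance threshold is the mean of the absolute 5th and 95th
percentiles of that fit — algebraically `max(1.645 σ̂, |μ̂|)`, invariant to
negating all inputs. A participant's condition difference (signed so
positive = better at SRT50 + 8 dB: faster RT, or higher proportion correct,
pooled over both sessions) is called significant when it exceeds the
threshold *in that direction*; the directional exceedance probability under
the null is 5% (both tails together carry 10% — the threshold is a per-tail
criterion, which is what the directional detection count uses). The fraction
of participants with a positive difference, regardless of size, is the
measure's maximum detection rate. Pooling condition means over both sessions
is this package's choice; using a single session would be equally defensible
with noisier differences.

## Problem sizes and runtime

Defaults follow the study design (18 participants, 30 SVT items and 5 SWIRT
lists per condition, test + retest). Calibration checks in the test suite
use 250-participant cohorts; the acceptance script uses 500 adaptive
tracks, a 20,000-draw null for the threshold rule, 10,000 null items for
the outlier detector, and 4 × 150-participant cohorts (item/list tables
redrawn per cohort so shared-material variability averages out). A full
default pipeline run — simulation, preprocessing, four GLMMs with backward
selection and interaction tests, and the threshold analysis — completes in
a few minutes on one CPU.

## Known limitations

* The Gamma shape is assumed constant across participants; real RT
  dispersion likely varies by person.
* The learning effect is a single multiplicative session factor per
  participant; order-dependent (within-session) learning is generated but
  never corrected, mirroring the analysis pipeline's scope.
* Backward selection explores single-term removals only (no exhaustive
  subset search), and AIC comparisons across non-converged candidates are
  skipped rather than penalized.
* Laplace (nAGQ = 1 equivalent) is the only integration scheme; for
  binary data with very small clusters adaptive quadrature would be more
  accurate, but crossed random effects preclude it in general.
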