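# Methods

## The attenuation model

The paradox simulator draws true per-subject effect pairs
(x\*, y\*) from a bivariate normal with common mean μ, between-subjects
variances σ²_x\*, σ²_y\* and correlation ρ\*. Observed session estimates add
independent Gaussian error; each estimate is conceptualised as the mean of M
trials whose per-trial error has standard deviation `err_sd_trial`, so the
estimate-level error variance is `err_sd_trial² / M`. Defaults (N = 100,
μ = 10, variances 80 or 1, ρ\* = 0.95, per-trial sd 5, M = 5) define the
two study scenarios; only this per-trial reading of the error scale is
simultaneously consistent with the attenuation closed form and all three
headline correlations (≈0.89 high-variance, ≈0.16 low-variance, ≈0.94 at
M = 3000). `expected_attenuation` implements Spearman's disattenuation
identity; `snr_attenuation` its symmetric M-trial special case
ρ\*/(1 + γ²/M), with γ² the per-trial *noise-to-signal* variance ratio
(the mathematically coherent orientation of the ratio).

## Reading measures

Fixations are assumed word-mapped; saccade detection and drift correction
are upstream concerns. The **first pass** of word w is the maximal run of
consecutive fixations on w starting at its first fixation, provided no word
to the right of w was fixated earlier; otherwise w has no first pass and
FFD, FPRT, RPD and FPReg are *missing* (NaN, never 0 — downstream lognormal
models must not see zeros). FFD is the first first-pass fixation's duration;
FPRT the run sum; FPReg indicates that the fixation immediately after the
run lands left of w; RPD (go-past) sums everything from the start of the
first pass up to, but excluding, the first later fixation right of w — for
the last word reached the window runs to the end of the sequence. TFT,
N_FIX and SKIP aggregate over all fixations. SKIP is the literal "never
fixated" definition. Word indices are screen-local and screens are not
revisitable, so cross-screen regressions cannot occur. Self-paced reading
times are consecutive keypress differences, with the first word timed from
screen onset.

## Synthetic corpora

The generator emulates the structure of a two-session naturalistic reading
study without claiming linguistic realism: no actual text, frequency norms
or language-model surprisal are produced. Five word-level predictors are
drawn from a latent Gaussian copula with a configurable correlation matrix
(defaults: length–frequency −0.6, length–surprisal 0.5,
frequency–surprisal −0.5, weak dependency-feature correlations — chosen to
echo the strong lexical intercorrelations of real text; no empirical matrix
for the target corpus is published, so these are plausibility-based) and
mapped to plausible marginals (integer lengths 1–20, continuous Zipf-like
log frequency, right-skewed positive surprisal, small-count dependency
features defined only on random word subsets; undefined words sit at the
predictor mean, i.e. zero after z-scoring, so no rows are dropped).

Per-subject random effects are drawn block-diagonally: one 2×2
(session-u, session-v) Gaussian per predictor with configurable sds and
correlation — exactly the structure the model estimates, so recovery tests
are well-posed. Responses come from the model's own linear predictor
(generation and fitting share `linear_predictor`) through the lognormal,
Bernoulli, or zero-inflated-Poisson observation model. Default effect sizes
sit at the magnitudes hierarchical fits of reading data typically report
(residual sd 0.44 log-ms, intercept sd 0.25, word-length slope 0.05,
smaller higher-level effects). Desk-scale defaults are 40 subjects × 2
sessions × 500 words; a full-scale preset (131 × 2 × 2233) exists but is
not exercised by the tests. All randomness flows from one seed through
`numpy.random.SeedSequence` spawning, so artifacts are bit-reproducible.

What passing recovery tests show: the estimator is calibrated *when the
generative model is true*. Real reading data violate it in known ways
(non-lognormal tails, serial autocorrelation, predictor measurement error,
cross-predictor random-effect correlations), so empirical reliabilities
carry caveats the synthetic study cannot expose.

The scanpath generator sweeps words left to right with stochastic skips,
capped-geometric refixations, and single-step regressions, and tracks every
word's measures *during* generation from the process's own knowledge of
first-pass boundaries — an oracle that is independent of the measure
implementation and is compared against it in the tests.

## The two-task model and its sampler

The likelihood families and links follow the standard GLMM convention: θ is
the linear predictor; the lognormal family models log y ~ Normal(θ, σ²),
the Bernoulli family uses the logit link, the zero-inflated Poisson the log
link with an intercept-only zero-inflation probability on the logit scale.
The session effect β_v is treatment-coded (second session label in sort
order). Predictors are z-scored over the fitted rows with the
population-sd convention; lagged (spillover) columns reuse their
predictor's location and scale. Subjects observed in a single session are
dropped with a warning — their cross-session correlation is undefined.
σ is shared across sessions within a fit. Spillover terms enter as random
slopes only by default; a flag adds fixed spillover effects.

Priors: β₀ ~ Normal(6, 1) (continuous) or Normal(0, 1) (binary/count);
slopes and the session effect ~ Normal(0, 1) continuous / Normal(0, 0.5)
otherwise; random-effect sds ~ Exponential(2); each 2×2 correlation block
~ LKJ(2) (equivalently (ρ+1)/2 ~ Beta(2, 2)); σ ~ Exponential(2);
zero-inflation intercept ~ Normal(0, 1). A tight preset
(β₀ ~ Normal(5.5, 0.1), slopes ~ Normal(0, 0.1)) plus doubled iterations is
the escalation path for hard-to-converge continuous fits. A tighter
binary-intercept scale was rejected deliberately: with a zero-mean
random-intercept block in the model, an overly tight global-intercept prior
makes the posterior reroute the grand mean into the random intercepts,
inflating their sd and corrupting the intercept-reliability estimate.

**Sampling.** Rather than exploring the full joint space (2 × (M+1) random
effects per subject), the sampler works on a collapsed posterior:

- *Lognormal:* conditional on the variance parameters, log y is jointly
  Gaussian, so the random effects integrate out exactly; the
  Woodbury/determinant identities reduce each evaluation to q×q algebra per
  subject (q = 2 × blocks), independent of word count. The Gaussian
  fixed-effect prior is conjugate here too, so β is collapsed as well; the
  sampled space is just {log sds, atanh correlations, log σ}.
- *Bernoulli / ZIP:* the random-effect integral has no closed form and is
  replaced by a per-subject Laplace approximation around the conditional
  mode (damped Newton), the approach of glmmTMB-style fitters; fixed
  effects remain in the sampled vector. The approximation error is
  O(1/n_i) in the per-subject observation count and is cross-checked
  against Monte-Carlo integration in the tests.

The collapsed posterior is explored with affine-invariant ensemble MCMC
(emcee) using differential-evolution moves; `chains` independent ensembles
start from overdispersed perturbations of a method-of-moments point, and
split-R̂ is computed across them (convergence threshold 1.01, with the
escalation preset as tie-break). Defaults mirror common practice: 4 chains
× 2000 iterations, 1000 warmup. Unconstrained transforms (log, atanh) carry
their Jacobians so the target equals the natural-parameter posterior
implemented in `log_density`. Fixed effects (lognormal) and per-subject
random effects (all families) are then drawn from their exact — or
Laplace-Gaussian — conditionals for a stride-thinned subset of draws,
yielding joint posterior samples. Reliability is summarized from the ρₘᵘᵛ
draws: posterior mean, central 95% credible interval, a flag for intervals
excluding zero, and a verbal band (poor < 0.3 ≤ low < 0.5 ≤ moderate
< 0.7 ≤ strong — documented conventions, configurable).

Numerical choices: non-positive-definite blocks and out-of-support
parameters yield −∞ (not exceptions) inside the sampler; walker counts
default to max(2·dim + 2, 16); zero-variance chains define R̂ = 1; the
split-R̂ uses the classic (non-rank-normalized) form and is cross-checked
against arviz. Degenerate inputs (constant predictors, < 2 sessions,
response/family mismatches) fail fast with errors.

## Variance decomposition and reporting

For continuous-family posteriors the decomposition reports posterior means
of σ and each between-subjects sd σₘ per session, and their ratio
γ̂ₘ = σ̂ₘ/σ̂ (the signal-to-noise ratio that governs attenuation); it is
undefined for binary/count families, where no residual σ exists. Posterior
point summaries are means; medians are available by flag. Back-transforms
map log-scale locations to milliseconds (exp), logits to probabilities
(inverse logit), and log rates to rates (exp).

## Problem sizes used in the checks

The recovery studies run 40 subjects × 2 sessions × 500 words with three
non-null predictor reliabilities {0.0, 0.3, 0.75}, two chains of 800
iterations (400 warmup) — settings chosen so a full 20-replicate
calibration study completes in minutes while keeping split-R̂ near 1. The
acceptance script uses 8 replicates of the same design.

## Known limitations

Cross-predictor random-effect correlations are neither generated nor
estimated (block-diagonal structure throughout). The Laplace-collapsed GLM
families inherit the approximation's small-sample bias for very sparse
subjects. Only two sessions/methods per fit are supported; shifted-lognormal
and ex-Gaussian response families, model comparison, and generative
eye-movement modelling are out of scope.
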