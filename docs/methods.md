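# Methods

This note records the statistical model, the numerical choices and the design
decisions behind `interlogit`, at the level of detail a maintainer or a
careful user needs to trust (or challenge) its output.

## Data model and the reconstructed example

All analyses operate on binary observations with three 0/1 variables:
response `Method` (1 = indirect cyber abuse) and predictors `Relationship`
(1 = prior offender–victim relationship) and `Motivation` (1 = expressive).
Because the predictors are binary, a dataset is equivalent to a 2×2 table of
per-cell totals and success counts (`CellTable`); `ObservationSet` is the
row-level view. The four predictor cells are indexed in "profile" order
(0,0), (1,0), (0,1), (1,1).

The worked example (n = 110) is reconstructed from its published summary: the
per-cell totals (18, 11, 29, 52) and proportions of indirect method
(0.22, 0.27, 0.34, 0.62) determine integer success counts (4, 3, 10, 32) by
rounding proportion × total. The reconstruction is frozen as constants after
validation: the implied per-cell log-odds (−1.25, −0.98, −0.64, 0.47) and all
three variable means (0.45, 0.57, 0.73) match the published values, and every
downstream table reproduces (see below). Row order on expansion is fixed
(cells lexicographic in (Relationship, Motivation), successes first) so
re-runs are byte-identical.

Two published tables contain label/column transpositions that the
reconstruction exposes. First, the sequential-deviance table: computed from
the data, dropping Motivation (leaving `{1, Relationship}`) gives deviance
143.81 and dropping Relationship (leaving `{1, Motivation}`) gives 144.23,
the reverse of the printed row labels; the BMA table corroborates the
computation, since the relationship-only model's printed BIC −363.84 equals
143.81 − 108 ln 110. Second, the simulation study's selection-count table:
the backward-elimination algorithm implemented here reproduces every printed
count within Monte-Carlo error once the "main effects" and "motivation-only"
columns are exchanged (e.g. at N = 1000 we find full/main-effects ≈ 956/44
where the table prints full/motivation ≈ 956/44; no fixed-level test of the
relationship term could make its selection rate fall from 33% at N = 110 to
0.4% at N = 500 as printed). This package reports each quantity under the
model that actually produces it.

## Maximum-likelihood fitting

`LogitGlm.fit()` maximizes the ungrouped (binary) likelihood by Fisher
scoring / IRLS: start at β = 0, Newton steps with step-halving whenever a
step would increase the deviance, convergence when the maximum absolute step
is below 1e−10, cap of 50 iterations. Internally rows are collapsed to their
distinct covariate patterns (at most 8 here) and fitted as grouped binomial
counts — the MLE, covariance and binary-convention deviance are unchanged,
and repeated fits inside the simulation study become cheap. Reported
residual df is always n_rows − p (hence 106 = 110 − 4 for the full model)
and deviance is −2 × binary log-likelihood.

Degenerate inputs: a rank-deficient design raises an error by default; with
`check_rank=False` (used by the simulation study) the fit proceeds through
least-squares pseudo-inverse Newton steps and is flagged. Probabilities are
clamped at 1e−12 in likelihood evaluation, so separated fits keep a finite
deviance; any fitted |η| > 30 triggers a quasi-separation warning and flag.
The covariance is the inverse observed Fisher information at the MLE
(verified against a finite-difference Hessian, and against statsmodels as an
independent oracle in the test suite).

Treatment (0/1 dummy) coding with level 0 as reference is used throughout.
Two parameterizations of the saturated 2×2 design are exposed — intercept +
Relationship + Motivation + product, and a single four-level factor with
(0,0) as baseline — and span the same column space; fitted probabilities and
deviance are invariant, and the level-4 coefficient equals the sum of the
three non-intercept coefficients of the conventional coding (1.72 = 0.27 +
0.61 + 0.84).

## Frequentist inference

`change_in_deviance` reports ΔD = D_reduced − D_current against an upper-tail
χ² with df equal to the residual-df difference, plus the display-convention
signed value (current − reduced). Unrounded internals are reported; printed
deltas in the source tables differ in the second decimal because they were
rounded from rounded deviances. `backward_select` tests the interaction
first (marginality respected during deletion); if retained the full model is
final, otherwise main effects are deleted iteratively, always dropping the
term with the largest non-significant p and refitting, with α = 0.05 by
default. `effect_translation` maps coefficient sums to odds ratios and to
probabilities (the "relative" and "absolute" effects).

## Bayesian logistic regression

The prior is multivariate normal; the worked example's vaguely-informative
default encodes the pilot-study hypotheses: μ = (−1, 0.1, 0.1, 1.1) with
diagonal variances (2, 0.5, 0.5, 2). (These are variances: the intercept
prior N(−1, 2) has 24% positive mass, the main-effect priors N(0.1, 0.5) have
44% negative mass, the interaction prior N(1.1, 2) 22% negative — checked
against the closed-form normal CDF.) A precision parameterization helper
mirrors the common alternative convention.

Sampling is plain random-walk Metropolis–Hastings: symmetric Gaussian
proposal with covariance tune² × (inverse Fisher information at the MLE),
tune = 1.1, falling back to the prior covariance when the MLE is unavailable
(e.g. zero rows). The chain starts at the MLE. Defaults are burn-in 10,000
and 100,000 retained iterations with thinning stride 1 (the source's text
mentions keeping every 100th draw while its code thins by 1; at this chain
length the summaries are indistinguishable, and stride is configurable).
Acceptance-rate diagnostics warn outside (0.05, 0.95) with a suggested
retuning scalar; on the example data the defaults accept ≈ 0.23, inside the
recommended (0.2, 0.5) band. (A sampler that derives its proposal from the
posterior-mode Hessian — prior included — proposes slightly smaller steps
and accepts ≈ 0.34; we follow the inverse-Fisher convention.)

Validation: the exact posterior under the example prior was pinned by four
independent 500k-draw chains and an MCMC-free importance-sampling estimate
(multivariate-t proposal at the posterior mode, effective sample size
≈ 287,000); both give interaction mean 1.130, SD 0.612. The published
summary (1.16/0.61) came from a chain with roughly 1000 effectively retained
draws, i.e. a Monte-Carlo standard error near 0.02, so comparisons in the
acceptance tests use the combined MC error of the two estimates. Posterior
functionals (per-profile linear predictors and probabilities with equal-tail
credible intervals, default 80%) reproduce the published cell summaries, e.g.
profile (1,1): 0.62 with 80% CrI (0.53, 0.70).

One caveat for users: with a flat prior the posterior mean does *not* equal
the MLE at this sample size (the likelihood is skewed in β; the intercept's
flat-prior posterior mean is −1.36 vs MLE −1.25). The test suite checks the
sampler against an importance-sampling oracle rather than against the MLE.

## Bayesian Model Averaging

All 2^k subsets of the candidate terms are enumerated (k ≤ 15 by default;
the cap exists because enumeration is exponential), with no marginality
constraint — the interaction may enter without its main effects, and on the
example data the top model is exactly `{1, Relationship:Motivation}`. Each
model is scored with BIC_k = D_k − df_k ln n with df_k = n − p_k. This
differs from the textbook D + p ln n by the additive constant n ln n, so
rankings and the softmax posterior probabilities exp(−BIC/2)/Σ exp(−BIC/2)
(uniform model prior, max-shifted for numerical stability) are identical
under either convention. The Occam's window retains models whose posterior
probability is within a factor (default 20) of the best model's, then
renormalizes; on the example data 6 of 8 models survive (the null and full
models are excluded) with cumulative unwindowed probability ≈ 0.94.

Inclusion probabilities sum the retained weights of models containing a
term. Model-averaged moments use the mixture over the retained window with
excluded models contributing a point mass at zero: mean = Σ w_i β̂_i,
variance = Σ w_i (se_i² + β̂_i²) − mean². The unconditional average is the
default because it is what the standard BMA summary reports (it reproduces
the published averaged interaction mean 1.07 and SD 0.67; the
conditional-on-inclusion variant, also exposed, gives 1.33). An aligned-text
"image plot" substitute renders the retained models with column widths
proportional to posterior probability.

## Simulation study

The generator mirrors the example's population: each subject falls in one of
the four predictor profiles with multinomial probabilities
(0.16, 0.10, 0.26, 0.48) and the outcome is Bernoulli with per-profile
probabilities (0.25, 0.25, 0.40, 0.70). Cell membership is resampled per
subject (not fixed margins), matching the published variability of subgroup
sizes. On the logit scale the design implies β = (−1.0986, 0, 0.6931,
1.2528): a null relationship effect, a moderate motivation effect, a large
interaction. Defaults are sample sizes (110, 500, 1000) and 1000 replicates
at α = 0.05 with Occam odds 20 — the study conditions, not tuning knobs.

Each replicate's dataset is shared between the deviance-selection and BMA
analyses (cheaper and lower-variance than independent draws; the source is
silent on this). Per replicate the study records the selected model and its
MLEs, BMA inclusion probabilities, averaged coefficients, per-profile
predictions from both strategies, and subgroup sizes; replicates with an
empty cell or a flagged fit are retained and counted as flagged. Quantiles
use NumPy's default linear interpolation. Reproducibility: the root seed
spawns one `SeedSequence` substream per (sample size, replicate), so studies
are byte-reproducible and replicates independent by construction.

Problem sizes: the acceptance tests run the study at 200 replicates on sizes
(110, 1000), which keeps the whole suite near ten seconds while leaving the
binomial Monte-Carlo error of the checked proportions below ±0.05; the
acceptance script runs the full 1000-replicate N = 1000 arm (the grouped
fast path makes a full study a few seconds of CPU). Stochastic checks
compare at 3 combined Monte-Carlo standard errors, with published quantiles
checked through empirical-CDF binomial bounds (the sampling distribution of
a quantile of a mixed discrete/continuous variable — many inclusion
probabilities sit exactly at 0 or 1 — is handled more robustly through the
CDF than through a density-based quantile standard error).

## What the synthetic generator does and does not emulate

It reproduces the joint distribution of three binary variables under the
stated cell probabilities — exactly the structure the inference strategies
see in the worked example. It does not emulate covariate measurement error,
within-source dependence (the example's rows are coded newspaper reports,
not independent victims), more than two predictors, or continuous
covariates. Passing tests therefore demonstrate the operating
characteristics of the four strategies under a correctly specified
low-dimensional design, not robustness to real-data pathologies.

## Known limitations

* Only the logit link and Bernoulli outcomes; no offsets or case weights.
* Model enumeration is exhaustive — no branch-and-bound shortcut — so the
  candidate-term cap matters for larger designs.
* MCMC diagnostics are deliberately minimal (acceptance rate, batch-means MC
  error, seed-to-seed comparison); users wanting R̂ or effective-sample-size
  machinery can export draws to CSV and use a dedicated toolkit.
* Exact Bayes factors are never computed; the BIC surrogate defines the
  model posteriors.
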