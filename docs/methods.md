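# Methods

## The scientific problem

The duration of untreated psychosis (DUP) — the number of days between
the onset of a first psychotic episode and first contact with mental
health services — is strongly right-skewed and is conventionally analysed
on the natural-log scale. The question this package is built to answer is
whether, once individual-level confounders are accounted for, any
meaningful share of the variability in log-DUP sits at the neighbourhood
(electoral ward) level, and if so whether that ward-level variability is
spatially structured (nearby wards resembling one another) or purely
idiosyncratic.

## The model ladder

For individual *j* in ward *i* (i = 1..K), with T_ij = ln(DUP days):

    T_ij  = mu_ij + e_ij,          e_ij ~ N(0, sigma_e^2)
    mu_ij = alpha + sum_k beta_k x_ijk + R_i + S_i

The covariates x are age in years (untransformed, so beta_age is the
change in expected log-DUP per year), an indicator for male sex, and six
0/1 dummies for ethnicity against a white British baseline (seven
categories in all). Two kinds of ward effect can enter:

* **Unstructured:** R_i ~ N(0, sigma_R^2) iid — exchangeable ward
  heterogeneity with no spatial pattern.
* **Spatially structured:** S follows the intrinsic conditional
  autoregression (ICAR): S_i | S_{-i} ~ N(mean of neighbours' S,
  sigma_S^2 / nu_i), where nu_i is ward i's number of contiguity
  neighbours. Note sigma_S is a *conditional* SD, not comparable in
  magnitude to sigma_R.

Six nested forms make up the ladder: (1) R only; (2) covariates + R;
(3) covariates only — a single-level model; (4) S only; (5) covariates +
S; (6) covariates + R + S. Fitting all six and comparing by DIC is the
analysis: if the single-level model 3 wins, ward membership carries no
useful information about DUP.

## Estimation

All six forms are fitted by a hand-written Gibbs sampler
(`carlm.sampler`). Every full conditional is conjugate:

* the fixed-effect vector (intercept + up to 8 slopes) is drawn jointly
  from its multivariate normal conditional (a joint draw mixes better
  than coordinate-wise updates);
* each R_i from a normal with precision n_i/sigma_e^2 + 1/sigma_R^2;
* each S_i sequentially from a normal with precision
  nu_i/sigma_S^2 + n_i/sigma_e^2 and mean the precision-weighted
  combination of the ICAR neighbour mean and the ward's residual mean;
* the variances from (possibly truncated) inverse-gamma conditionals.

The ICAR prior is improper (invariant to a constant shift per connected
component), so after every spatial scan S is recentred to sum to zero
within each component and the removed mean is absorbed into the
intercept. For graphs with several components the absorbed shift is the
case-weighted average of the per-component means; this is exact in the
connected case, which is the only one the default study design uses. The
sigma_S^2 conditional uses the pairwise-difference sum of squares over
edges with degrees-of-freedom K − c (c = number of connected
components), the rank of the ICAR quadratic form. Isolated wards are an
error under spatial forms unless explicitly permitted, in which case
their S_i is pinned at zero.

**Priors** ("minimally informative" defaults): Normal(0, 100^2) on the
intercept and slopes; Uniform(0, 100) on each standard deviation. A
Gamma(0.001, 0.001) prior on precisions is selectable for sensitivity
analysis; uniform-on-SD is the default because vague gamma priors are
known to behave badly exactly where this analysis lives — variance
components near zero. Under the uniform-SD prior the variance full
conditional is an inverse-gamma((df−1)/2, SS/2) truncated to
(0, upper^2), sampled by inverse-CDF through the regularised incomplete
gamma function.

**Initialisation and chains.** Chain c starts from the least-squares
fixed effects jittered by c times the coefficient standard-error scale,
with variances at the residual-variance estimate times (0.5, 1, 2)
cycling by chain — overdispersed starts so split-R-hat is meaningful.
Library defaults are 2 chains, 10,000 burn-in and 20,000 retained sweeps
(thin 1); the conjugate sampler mixes fast at this problem size
(roughly 0.3 ms per sweep for 32 wards and ~300 cases), so the pipeline,
tests and acceptance script use shorter, explicitly-passed runs —
typically 2,000–20,000 retained sweeps — which the diagnostics show are
ample for these posteriors.

**Determinism.** All randomness flows from a single integer seed through
NumPy `SeedSequence` spawns (one stream per chain; in the pipeline, one
derived seed per model; in the generator, separate streams for ward
effects, counts and individuals), so identical configuration gives
byte-identical outputs.

## Model assessment

* **DIC** = Dbar + pD with pD = Dbar − D(posterior means), where the
  deviance is −2 × the Gaussian log-likelihood *conditional on the ward
  effects* (random effects "in focus"). This is the plug-in convention
  under which a well-identified k-parameter fixed-effects model has
  pD ≈ k, and near-zero variance components cost almost nothing — the
  behaviour the ladder comparison relies on.
* **Summaries** are posterior medians with equal-tailed 95% credible
  intervals, pooled across chains (the WinBUGS-era reporting
  convention; no HPD intervals).
* **Area-level variance share.** Because sigma_S^2 is conditional, the
  spatial contribution is measured by the empirical variance of the
  current S vector at each retained iteration:
  share = 100 · (sigma_R^2 + var(S)) / (sigma_R^2 + var(S) + sigma_e^2),
  summarised by its median and 95% interval. A point-estimate mode
  (ratio at posterior means) is available; the per-iteration ratio is
  the default and is the wider, more honest summary of the two since
  interval width propagates into it. Model forms with no area block
  report "not applicable".
* **Convergence**: classic split-chain potential-scale-reduction
  (R-hat) per parameter, warning above 1.05; requires at least two
  chains. (An independent implementation in `arviz` is used as a
  cross-check in the test suite only.)

## The synthetic-data generator

No patient-level data ship with the package, so `carlm.simulate` draws
complete datasets from the generative process of model 6 on a
rook-contiguity lattice (default 4×8 = 32 wards, a stand-in for an urban
ward map). Defaults emulate the study conditions the package targets:

| parameter | default | rationale |
|---|---|---|
| mean cases/ward | 9.8 | 314 cases over 32 wards; counts are 1 + Poisson(mean−1), so no ward is empty and the median count is ~8 (range ~1–30) |
| sigma_e | 1.9 | residual SD of log-DUP |
| sigma_R, sigma_S | 0.12, 0.19 | small ward-level components |
| beta_age | 0.053 | per-year effect on log-DUP |
| beta_sex | 0.24 | men vs women |
| ethnicity contrasts | −0.13, 0.21, −0.74, −1.2, −0.83, −0.43 | six contrasts vs white British |
| alpha | 2.23 | chosen so the marginal median DUP is exp(4.24) ≈ 69.5 days given the covariate means under the default covariate distributions |
| age | Uniform(16, 64) | the eligibility window |
| sex | fair coin | no reported imbalance to emulate |
| ethnicity probs | (.30, .10, .25, .15, .05, .08, .07) | a plausible inner-city first-episode mix; configurable |
| diagnosis | affective with prob 0.25 | typical first-episode case mix; used only for subgroup reruns |

ICAR vectors are simulated on the proper sum-to-zero subspace via
eigen-decomposition of the graph Laplacian (covariance sigma_S^2 times
the Laplacian pseudo-inverse) — the standard identifiable representation
of the intrinsic model.

What the generator deliberately does **not** emulate: referral pathways,
censoring or rater error in DUP, informative missingness, the exclusion
mechanism for cases of no fixed abode, real ward geography, or any
dependence of covariates on ward. Passing tests therefore demonstrate
that the machinery is correct under the stated generative model, not
that the model is adequate for any particular real dataset.

## Numerical and design choices

* **Zero DUP**: rejected by default (log undefined); an explicit option
  replaces 0 with 0.5 days and logs the substitution. Silent transforms
  corrupt analyses.
* **Empty wards**: retained in the graph by default (they still carry a
  spatial effect and contribute smoothing); `restrict_to_observed`
  drops them for the stricter convention of analysing only wards with
  cases.
* **Age** enters uncentred by default so coefficients stay on the
  per-year scale; a centring flag exists for sampler conditioning.
* **Covariate column order** is fixed (age, sex, six ethnicity dummies)
  so reports line up across runs.
* Variance draws are floored at 1e-12; the uniform-SD update requires
  df > 1 and raises otherwise (a graph whose ICAR rank is below 2
  genuinely cannot inform a scale parameter under that prior).
* Degenerate chains (zero spread) give pD = 0 exactly; empty sample
  sets are an error, not a NaN.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the recovery studies at
the study scale (32 wards, ~300 cases) with 50 replicate full-model fits
for interval coverage and 20 replicates per scenario for
model-selection recovery, using 2,000–2,600 sweeps per fit — sizes at
which the conjugate sampler's Monte-Carlo error is far inside the
tolerances being checked, as the conjugate-oracle and R-hat results
confirm.

## Known limitations

* The ICAR spatial model is intrinsic only: no proper-CAR spatial
  autocorrelation parameter, no spatio-temporal extension, and no
  Metropolis fallback for non-conjugate extensions.
* The ladder's covariate set is fixed to age, sex and ethnicity;
  arbitrary extra ward-level covariates are outside the fitted forms.
* DIC is the only model-comparison criterion (no WAIC/LOO).
* With several graph components the intercept-absorption of the
  recentred spatial means is a case-weighted compromise (exact when the
  graph is connected).
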