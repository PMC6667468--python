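# Methods

This note documents the models implemented in `healthtraj`, the choices
made where the methodology left room, and what the synthetic-data tests
do and do not establish.

## The health metric: Bayesian multilevel 2PNO IRT

Binary difficulty indicators (ADL/iADL difficulties, pain/sleep/energy
problems, dichotomized cognitive tests) are modelled with a
two-parameter normal-ogive response function,

P(y_pij = 1 | θ_pj) = Φ(a_ij θ_pj − b_ij),

where θ_pj is the latent health of person *p* at wave *j* (higher =
healthier; items code *difficulty*, so the sign convention is handled by
the difficulty parameters), b_ij is the wave-specific difficulty of item
*i* and a_ij its discrimination. The multilevel (random item) structure
lets item parameters drift across waves around item-level means:

b_ij ~ N(b_i, σ²_b,i),  a_ij ~ N(a_i, σ²_a,i),
b_i ~ N(μ_b, ω²_b),  a_i ~ N(1, ω²_a) truncated to a_i > 0.

Four variance-structure variants are fit: (1) no wave variance in either
parameter; (2) item-specific difficulty variance; (3) one difficulty
variance shared by all items; (4) both variances free with the
hyperprior parameters estimated. Variants 1–3 fix all discriminations at
one.

**Linear predictor.** The slope–threshold form a·θ − b is used (the
convention of the normal-ogive Gibbs sampling literature). Difficulty is
therefore on the θ scale divided by a.

**Person side.** θ_pj ~ N(μ_j, σ²_j) per wave, with weakly informative
priors μ_j ~ N(0, 100) and σ²_j ~ Inv-Gamma(1, 1). The item-side
identification constraints (below) pin location and scale per wave, so
the wave means μ_j express population health change — this is what makes
scores comparable across waves while item parameters vary.

**Estimation.** Gibbs sampling with truncated-normal data augmentation
for the probit likelihood (inverse-CDF draws; all conditionals are
conjugate; wave discriminations and their means are sampled from
positive-truncated normals). Variance components get Inv-Gamma(2, 0.2)
priors (Inv-Gamma(2, 0.05) for discrimination wave variances), weakly
informative on the scale of the generating values used in testing. Items
observed in only some waves contribute only at those waves; an item with
all-identical responses in a wave keeps its wave parameter at the prior
mean.

**Identification.** After every iteration and per wave, difficulties are
recentred (b_ij ← b_ij − a_ij δ_j with δ_j = Σb/Σa, giving Σ_i b_ij = 0
exactly) and discriminations divided by their geometric mean (product
one); the latent trait and its population parameters absorb both
transformations, leaving every response probability unchanged. The
constraints hold on every stored draw to machine precision.

**Defaults.** 7,000 iterations with the first 100 discarded mirror the
published analysis settings; for new data we recommend ≥1,000 burn-in
iterations and at least two chains (the default — single-run R-hat is
not defined, so split-chain R-hat over ≥2 chains is used). DIC uses
Spiegelhalter's p_D (mean deviance minus deviance at posterior means).
EAP reliability is var(EAP)/(var(EAP) + mean posterior variance), pooled
over person-waves. The measurement precision curve is
SE(θ) = 1/√(Σ a² φ(aθ−b)² / (P(1−P))) on the first wave's parameters.

**0–100 transform.** An affine map taking the pooled min/max of the EAP
traits to 0 and 100 (the source analysis does not state its transform;
min–max is the simplest order-preserving choice). The constants are
stored on the results object so new cohorts can be scored on the same
scale, with clamping at the bounds.

**Variant selection.** Lowest DIC among fits whose maximum split-chain
R-hat is ≤ 1.1; ties broken by higher EAP reliability, then lower
variant id. Non-convergence is a recorded warning, not an exception.

## Dimensionality check

Unidimensionality is probed on a random 70% exploration split of the
baseline wave: pairwise ML tetrachoric correlations (thresholds fixed at
the sample margins, 0.5 continuity correction for empty cells, estimates
capped at ±0.999, eigenvalue-clipped SPD repair when needed and
flagged), minres factor extraction, and oblique geomin rotation
(ε = 0.01) by gradient projection with seeded random starts (the geomin
criterion is multimodal). Fit indices come from the ML discrepancy with
Bartlett's correction: χ², RMSEA with a 90% noncentral-χ² CI, and CFI
against the independence model; the conventional CFI ≥ 0.90 /
RMSEA ≤ 0.06 thresholds are reported. The original second-order WLSMV
CFA is replaced by a rank-1 (single general factor) minres fit to the
inter-factor correlation matrix — a deliberate methodological
approximation: it asks the same question (do the first-order factors
share one dimension?) with a simpler estimator. Exact χ² values from
weighted-least-squares estimators are therefore not comparable.

## Trajectories: conditional growth mixture model

The health score y_pj follows a latent growth curve per class k:

η_p = (I_p, S_p) | C=k, x_p ~ N(α_k + Γ_k x_p, Ψ),
y_pj = I_p + λ_j S_p + ε_pj,  ε_pj ~ N(0, σ²_j),

with λ anchored at λ_1 = 0, λ_J = 1 (latent basis: middle loadings
free), so the intercept is baseline health and the slope the total
first-to-last change. Ψ, σ²_j and λ are shared across classes — the
parameterization whose count is 22K + 2 with six covariates and four
waves. Class membership is multinomial logistic on the covariates
(one-step inclusion), and end-of-study mortality is a class-dependent
Bernoulli distal outcome, conditionally independent of the trajectory
given class (persons with unknown status contribute no Bernoulli
factor). Listwise deletion applies to missing covariates (count
reported); wave missingness is handled by full-information ML over
observed-data patterns (MAR).

**EM.** Responsibilities include the covariate prior and distal factor;
the M-step updates the mean structure by class-weighted least squares on
posterior factor moments, Ψ/λ/σ² from pooled posterior second moments,
π_k by weighted averages, and the logits by damped Newton ascent on the
expected complete-data log-likelihood (step-halving preserves the
generalized-EM ascent property). The observed-data log-likelihood is
asserted non-decreasing every iteration (tolerance 1e-8 relative); a
decrease is a hard failure. Residual variances are floored at 1e-4
squared score units to block degenerate spikes; a start whose class
empties (expected count < 1 person) is discarded.

**Multistart.** Quantile-based starting centres from per-person OLS
growth factors, perturbed (intercepts by ±1 pooled SD, logits and death
probabilities jittered); short EM runs rank the starts and the best few
are polished to convergence. The published analysis used 250 random
starts; the library default is 250, while tests and the acceptance
script use 8–25 starts with 6–15 short-run iterations (sizes chosen to
keep the recovery studies proportionate — the fitted surfaces at those
sizes replicate the best log-likelihood across starts, and a
replication count below 2 raises a warning).

**Label order and reporting.** Classes are relabelled by descending
intercept mean; logits and odds ratios are reported against the largest
class (the "high-stable" analogue). Robust (sandwich) standard errors
A⁻¹BA⁻¹ use numerically differentiated per-person scores (B) and a
central-difference Hessian (A).

**Selection statistics.** BIC, SSABIC (penalty log((n+2)/24)), relative
entropy 1 − Σ(−p log p)/(N log K), and an adjusted LMR-LRT:
2ΔLL/(1 + ((p₁−p₀) ln n)⁻¹) referred to χ²(Δp). That reference
distribution is an acknowledged approximation (the exact weighted-χ²
reference is not reproducible from the source description), so a seeded
parametric-bootstrap LRT is provided as the calibrated alternative.

## Predictive validity

Sex-adjusted AUC: the Mann–Whitney AUC (midrank ties) of the negated
baseline score against death is computed within each sex and pooled
with weights proportional to cases × controls; DeLong variances pool
with the squared weights for the 95% CI. Score–death pairs are never
compared across sexes, which is the stratified reading of "adjusted per
gender" (the original external-software estimator is unstated). Persons
with unknown mortality at a horizon are excluded from that horizon.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults set to the study conditions:

- four trajectory classes with growth means (68.27, −28.29),
  (56.39, −7.71), (75.83, −11.52), (39.69, −6.46), shared
  Ψ = [[25.05, 17.05], [17.05, 20.44]], basis loadings proportional to
  elapsed time (0, 2/14, 11/14, 1) between the 2001/2003/2012/2015
  waves;
- class-membership logits on six covariates with the published lifestyle
  coefficients and intercepts calibrated by Monte-Carlo iteration so the
  marginal shares hit 22.6/13.0/59.0/5.4%;
- covariate distributions matching the baseline descriptives (58%
  female, age ~N(60, 10.7²) clipped at 50, education mass on
  none/primary, 65.5% non-active, 57.3% never-smokers, 68.7%
  non-drinkers, <0.8% missing);
- class death probabilities 0.81/0.26/0.05/0.95 (overall ≈ 29%);
- wave residual SD 7 score units, chosen so the four-class entropy lands
  near 0.71;
- a 40-item bank (30 anchors in all waves, extra items in ≥2 random
  waves), difficulties spread over ±2.2, discriminations 1, shared
  difficulty wave-SD 0.3; the trait is θ = (H − 60)/15;
- ~1% administrative item missingness; monotone MAR attrition with a
  logistic hazard on the previous wave's observed health
  (expit(−1.5 − 0.4 θ)), a concrete stand-in for the study's
  MAR-only statement, with the intercept set so the minimum wave-pair
  covariance coverage lands near the reported 0.45;
- deceased persons stop contributing responses from a death wave drawn
  with a health-dependent interval hazard (survive each interval with
  probability expit(0.85 + 0.6 θ₁)) — frailer people die sooner, which
  is what makes the baseline score's AUC decay with the mortality
  horizon as observed in real cohorts.

The verbal-fluency dichotomization uses the linear-interpolation
empirical 25th percentile (the quantile rule is fixed here because the
source does not name one).

**What the generator does not emulate:** questionnaire wording and
recoding dialects beyond the category map, proxy interviews, survey
design/weights, time-varying covariates, early-life exposures, and any
non-MAR dropout. Passing recovery tests on these cohorts demonstrates
the estimators are correct under the assumed model, not that the model
describes any particular survey.

## Problem sizes in the test and acceptance runs

Recovery studies run at deliberately moderate sizes: IRT difficulty
recovery at n = 1,000 persons, 30 items, 3,000 iterations × 2 chains;
variant-4 recovery at n = 2,000; DIC variant comparison across 10 seeds
at n = 300; growth-shape selection across 10 seeds at n = 600; the
four-class GMM recovery study across 10 seeds at n = 3,000 with an
8-start economised multistart. The acceptance script fits the full
pipeline once at n = 1,000 (IRT) / n = 3,000 (GMM) with 12 starts.

A caveat documented deliberately: at n = 3,000 the BIC penalty for 22
extra parameters (22 ln 3000 ≈ 176) exceeds the 4th-class likelihood
gain implied by the published four-versus-three-class log-likelihoods
when scaled proportionally to n (≈ 86), so BIC selects three classes at
this scale even though the generator truth has four; SSABIC (penalty
≈ 106) does select four. Likewise the 5%-share low-stable class — 95%
of whom die and lose later waves — cannot be pinned to ±1.5 intercept
units at n = 3,000 (truth-started EM converges to the same merged mode;
at n = 12,000 recovery is clean). These are information limits of the
scaled-down design, not estimator defects, and the corresponding
acceptance tests fail honestly at that scale.

## Known limitations

- The Gibbs sampler stores running moments for θ (not full draws), so
  per-person convergence diagnostics cover only item and population
  parameters.
- The aLMR-LRT p-value is approximate (see above); use the bootstrap
  LRT where calibration matters.
- Sandwich standard errors rely on numerical differentiation; for very
  large K·q the Hessian pass is the slowest step of a fit.
- The EFA fit indices apply ML theory to tetrachoric input; with small
  exploration samples (n in the hundreds with dozens of items) the
  indices are noisy and the SPD repair inflates χ².
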