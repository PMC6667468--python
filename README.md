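# healthtraj

Health-trajectory modelling for ageing cohorts: a Bayesian multilevel
item-response-theory health metric, followed by conditional growth
mixture modelling of its trajectories with lifestyle covariates and a
mortality distal outcome.

## Who this is for

Epidemiologists and biostatisticians working with multi-wave panels of
older adults (the canonical case: four survey waves with ~40 binary
functional-difficulty items, lifestyle covariates, and end-of-study
mortality, as in studies like the Mexican Health and Aging Study) who
want to (a) place persons on a common 0–100 health scale across waves
even when item sets change, and (b) identify latent subgroups with
distinct ageing trajectories and see which lifestyle factors predict
membership. A synthetic-cohort generator with study-realistic defaults
makes every stage runnable and testable without any survey download.

## The models

**Stage 1 — health metric.** A two-parameter normal-ogive IRT model
with wave-varying (random) item parameters:

    P(y_pij = 1 | θ_pj) = Φ(a_ij θ_pj − b_ij),
    b_ij ~ N(b_i, σ²_b,i),   a_ij ~ N(a_i, σ²_a,i),
    b_i ~ N(μ_b, ω²_b),      a_i ~ N(1, ω²_a),

fit by Gibbs sampling with probit data augmentation. Four
variance-structure variants (none / item-specific / shared difficulty
variance / both parameters free) are compared by EAP reliability, DIC,
measurement precision (SE(θ) < 0.5 over the trait range) and split-chain
R-hat. Per wave, difficulties sum to zero and discriminations multiply
to one on every draw, which links the metric across waves through the
anchor items. EAP trait estimates are mapped to a 0–100 score (higher =
healthier).

**Stage 2 — trajectories.** A conditional growth mixture model on the
scores with a latent-basis growth curve (loadings anchored 0 and 1,
middle loadings free), class-specific growth means and covariate
effects, shared growth covariance Ψ and wave residuals, multinomial
logistic class membership (one-step covariate inclusion), and death by
end of follow-up as a class-dependent Bernoulli distal outcome.
Estimation is multistart EM under FIML for missing waves; class counts
are compared by BIC, SSABIC, entropy and the adjusted LMR-LRT (plus a
parametric-bootstrap LRT).

Supporting stages: split-sample tetrachoric EFA with geomin rotation
and a general-factor check (unidimensionality), and sex-stratified ROC
analysis of the baseline score against mortality at increasing horizons
(predictive validity). See `docs/methods.md` for assumptions, priors,
defaults and limitations.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from healthtraj import (HealthIRTModel, GrowthMixtureModel, GrowthSpec,
                        default_config, generate_cohort)
from healthtraj.simulate import COVARIATE_COLUMNS, covariate_design_frame

# a synthetic four-wave cohort under the study-condition defaults
cohort = generate_cohort(default_config(n_persons=1000, seed=7))

irt = HealthIRTModel(cohort.responses, variant=3).fit(
    n_iterations=1500, n_burnin=150, n_chains=2, seed=7)
print(irt.summary())

scores = irt.scores().rename(columns={"score_0_100": "score"})[
    ["person_id", "wave", "score"]]
spec = GrowthSpec(pattern="latent_basis", n_classes=4,
                  covariates=tuple(COVARIATE_COLUMNS), distal_outcome=True)
gmm = GrowthMixtureModel(scores, covariate_design_frame(cohort.covariates),
                         cohort.mortality, spec).fit(n_starts=12, seed=7)
print(gmm.summary())
```

prints (about two minutes on one CPU):

```
Bayesian multilevel 2PNO IRT fit
========================================
variant:            3
persons:            1000
items:              40
waves:              4
chains x draws:     2 x 1350
EAP reliability:    0.916
DIC:                246778.3 (p_D = 23511.1)
SE<0.5 fraction:    1.00
max R-hat:          1.003 (ok)
mean score by wave: 1:61.9, 2:60.9, 3:52.3, 4:50.5

Growth mixture model (latent_basis, 4 classes)
========================================================
persons: 967   waves: 4   covariate-dropped: 33
LL = -11598.27   parameters = 90   BIC = 23815.22   SSABIC = 23529.39
entropy = 0.594   best-LL replications = 2
loadings: [0.0, 0.157, 0.767, 1.0]
Psi: [[34.71, 9.8], [9.8, 9.78]]
residual variances: [60.52, 79.39, 74.86, 75.05]
class 1 (reference): share 0.370  intercept 68.24  slope -11.66  death prob 0.000
class 2: share 0.291  intercept 62.43  slope -13.64  death prob 0.106
class 3: share 0.204  intercept 58.24  slope -36.87  death prob 0.725
class 4: share 0.135  intercept 41.36  slope -8.79  death prob 0.667
```

Reading it: the metric is highly reliable (EAP reliability 0.92), the
sampler converged (R-hat 1.003), and mean health declines across waves
(61.9 → 50.5). The mixture then finds a healthy stable class, a steeply
declining class with high death probability, and a low-level class —
classes are ordered by baseline health, with the largest class as the
reference for odds ratios (`gmm.odds_ratios()`). The free loadings
(0.157, 0.767) track the uneven wave spacing. At n = 1,000, 90
parameters are generous — compare class counts with
`healthtraj.select_n_classes` before interpreting.

The same stages are available as a CLI
(`healthtraj simulate | fit-irt | check-dimensionality | fit-gmm |
validate-roc | run-all`), with `run-all` driving the full pipeline from
a YAML config and writing every intermediate artifact plus a
consolidated report.

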