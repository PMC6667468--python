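"""Synthetic ageing-cohort generator.

Emulates the statistical structure of a four-wave panel of older adults in
which binary functional-difficulty items measure a declining latent health
trait, persons belong to latent trajectory classes predicted by lifestyle
covariates, and mortality at the end of follow-up depends on class.

The generative model (mirroring the analysis models downstream):

* person-level growth factors ``(I_p, S_p)`` drawn from a class-conditional
  bivariate normal ``N(alpha_k + Gamma_k x_p, Psi)``;
* a latent health *score* per wave ``H_pj = I_p + lambda_j * S_p + e_pj``
  with latent-basis loadings ``lambda`` anchored at 0 and 1 and
  occasion-specific residual ``e_pj ~ N(0, sigma_j^2)``;
* an IRT-scale trait ``theta_pj = (H_pj - center) / scale``;
* binary item responses ``Bernoulli(Phi(a_ij * theta_pj - b_ij))`` under a
  two-parameter normal-ogive model with wave-varying item parameters
  ``b_ij ~ N(b_i, sigma_b,i^2)``, ``a_ij ~ N(a_i, sigma_a,i^2)`` (a > 0);
* class membership from a multinomial logistic model on the covariates;
* end-of-study mortality ``Bernoulli(pi_k)`` with class-specific
  probabilities, plus a monotone MAR attrition hazard on the previous
  observed health score and uniform item-level administrative missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "default_config",
    "calibrate_class_intercepts",
    "generate_cohort",
    "covariate_design_frame",
    "impose_missingness",
    "apply_recoding",
    "dichotomize_fluency",
    "write_cohort_csv",
    "read_panel_csv",
]

# Baseline covariate frequencies of the cohort being emulated (2001 wave):
# ~58% female, mean age 60 (SD 10.7), education mass on none/primary,
# 65.5% not physically active, 57.3% never smokers, 68.7% non-drinkers.
_FEMALE_RATE = 0.579
_AGE_MEAN, _AGE_SD = 59.99, 10.66
_EDU_PROBS = (0.235, 0.532, 0.080, 0.050, 0.040, 0.030, 0.020, 0.013)
_NON_ACTIVE_RATE = 0.655
_NEVER_SMOKER_RATE = 0.573
_NON_DRINKER_RATE = 0.687

# Four-class truth used as defaults: trajectory classes ordered
# decliners, moderate-stable, high-stable (reference), low-stable.
_CLASS_NAMES = ("decliners", "moderate_stable", "high_stable", "low_stable")
_GROWTH_MEANS = np.array(
    [[68.27, -28.29], [56.39, -7.71], [75.83, -11.52], [39.69, -6.46]]
)
_GROWTH_COV = np.array([[25.05, 17.05], [17.05, 20.44]])
_DEATH_PROBS = np.array([0.81, 0.26, 0.05, 0.95])
_TARGET_SHARES = np.array([0.226, 0.130, 0.590, 0.054])
# Lifestyle class logits (non-active, never-smoker, non-drinker) vs the
# high-stable reference, from the four-class conditional solution; the
# socio-demographic coefficients (female, std. age, std. education) are
# plausible fill-ins since only lifestyle logits are tabulated.
_CLASS_LOGITS_X = {
    "decliners": (0.33, -0.39, 0.19, 0.10, 0.50, -0.20),
    "moderate_stable": (-0.06, -0.28, 0.04, 0.10, 0.10, -0.10),
    "low_stable": (2.17, -0.58, 0.48, 0.20, 0.60, -0.30),
}

COVARIATE_COLUMNS = [
    "non_active",
    "never_smoker",
    "non_drinker",
    "sex",
    "age",
    "education",
]


def _covariate_design(cov: pd.DataFrame, fill: bool = True) -> np.ndarray:
    """Design matrix for class-membership / growth-factor regressions.

    Binary lifestyle indicators enter raw; age and education are
    standardised so the logit intercepts stay interpretable. With
    ``fill`` missing values become 0 (the covariate mean/reference).
    """
    x = np.column_stack(
        [
            cov["non_active"].to_numpy(float),
            cov["never_smoker"].to_numpy(float),
            cov["non_drinker"].to_numpy(float),
            cov["sex"].to_numpy(float),
            (cov["age"].to_numpy(float) - _AGE_MEAN) / _AGE_SD,
            (cov["education"].to_numpy(float) - 2.0) / 1.5,
        ]
    )
    return np.nan_to_num(x) if fill else x


def covariate_design_frame(cov: pd.DataFrame) -> pd.DataFrame:
    """Standardised covariate design as a DataFrame keyed by person_id,
    preserving missing values (so downstream listwise deletion applies)."""
    df = pd.DataFrame(_covariate_design(cov, fill=False), columns=COVARIATE_COLUMNS)
    df["person_id"] = cov["person_id"].to_numpy()
    return df


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``class_logit_coefficients`` has one row per *non-reference* class
    (intercept followed by one coefficient per covariate design column);
    ``reference_class`` indexes the class whose logits are fixed at zero.
    """

    n_persons: int
    n_waves: int = 4
    n_anchor_items: int = 30
    n_extra_items: int = 10
    item_difficulty_means: np.ndarray | None = None
    item_discrimination_means: np.ndarray | None = None
    difficulty_wave_sd: float | np.ndarray = 0.3
    discrimination_wave_sd: float | np.ndarray = 0.0
    n_classes: int = 4
    reference_class: int = 2
    class_logit_coefficients: np.ndarray | None = None
    growth_means_per_class: np.ndarray = field(
        default_factory=lambda: _GROWTH_MEANS.copy()
    )
    covariate_effects_per_class: np.ndarray | None = None
    growth_covariance: np.ndarray = field(default_factory=lambda: _GROWTH_COV.copy())
    basis_loadings: np.ndarray | None = None
    residual_sd_per_wave: np.ndarray | None = None
    distal_death_prob_per_class: np.ndarray = field(
        default_factory=lambda: _DEATH_PROBS.copy()
    )
    admin_missing_rate: float = 0.01
    covariate_missing_rate: float = 0.005
    attrition_hazard: tuple[float, float] | None = (-1.5, -0.4)
    death_timing: tuple[float, float] = (0.85, 0.6)
    theta_center: float = 60.0
    theta_scale: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_items = self.n_anchor_items + self.n_extra_items
        if self.item_difficulty_means is None:
            self.item_difficulty_means = np.linspace(-2.2, 2.2, n_items)
        if self.item_discrimination_means is None:
            self.item_discrimination_means = np.ones(n_items)
        if self.basis_loadings is None:
            # default: proportional to elapsed time 0/2/11/14 years
            t = np.array([0.0, 2.0, 11.0, 14.0])[: self.n_waves]
            self.basis_loadings = t / t[-1]
        if self.residual_sd_per_wave is None:
            self.residual_sd_per_wave = np.full(self.n_waves, 7.0)
        if self.covariate_effects_per_class is None:
            self.covariate_effects_per_class = np.zeros(
                (self.n_classes, 2, len(COVARIATE_COLUMNS))
            )
        if self.class_logit_coefficients is None:
            if self.n_classes == 1:
                self.class_logit_coefficients = np.zeros((0, 7))
            else:
                rows = []
                names = [n for i, n in enumerate(_CLASS_NAMES) if i != 2]
                for name in names[: self.n_classes - 1]:
                    rows.append((0.0,) + _CLASS_LOGITS_X[name])
                self.class_logit_coefficients = np.array(rows)
        for arr in (
            "item_difficulty_means",
            "item_discrimination_means",
            "basis_loadings",
            "residual_sd_per_wave",
            "growth_means_per_class",
            "growth_covariance",
            "class_logit_coefficients",
            "covariate_effects_per_class",
            "distal_death_prob_per_class",
        ):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        self.validate()

    def validate(self) -> None:
        lam = self.basis_loadings
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise ValueError("basis loadings must be anchored at 0 and 1")
        psi = self.growth_covariance
        if not np.allclose(psi, psi.T):
            raise ValueError("growth covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(psi) <= 0):
            raise ValueError("growth covariance must be positive-definite")
        if np.any(self.item_discrimination_means <= 0):
            raise ValueError("discrimination means must be positive")
        if np.any(np.asarray(self.difficulty_wave_sd) < 0) or np.any(
            np.asarray(self.discrimination_wave_sd) < 0
        ):
            raise ValueError("wave SDs must be non-negative")
        pi = self.distal_death_prob_per_class
        if np.any((pi < 0) | (pi > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")
        if not 0 <= self.admin_missing_rate <= 1:
            raise ValueError("admin_missing_rate must lie in [0, 1]")
        if self.class_logit_coefficients.shape[0] != self.n_classes - 1:
            raise ValueError("need one logit row per non-reference class")


@dataclass
class SyntheticCohort:
    """A generated cohort: observed data plus the generating truth."""

    responses: pd.DataFrame  # person_id, wave, item_id, response (0/1/NA)
    covariates: pd.DataFrame
    mortality: pd.DataFrame  # person_id, dead (0/1/NA)
    truth: dict
    config: SimConfig

    def observed_scores(self) -> pd.DataFrame:
        """Long table of the latent health score at observed person-waves."""
        h = self.truth["health_score"]
        present = self.truth["present"]
        pid, wave = np.nonzero(present)
        return pd.DataFrame(
            {
                "person_id": pid,
                "wave": wave + 1,
                "score": h[pid, wave],
            }
        )


def default_config(n_persons: int, seed: int, **overrides) -> SimConfig:
    """A study-condition config with class intercepts calibrated so the
    marginal class shares match the four-class solution (22.6/13.0/59.0/5.4%).
    """
    cfg = SimConfig(n_persons=n_persons, seed=seed, **overrides)
    if cfg.n_classes > 1:
        cfg = calibrate_class_intercepts(cfg, _TARGET_SHARES[: cfg.n_classes])
    return cfg


def _class_probs(coefs: np.ndarray, ref: int, x: np.ndarray) -> np.ndarray:
    n, _ = x.shape
    n_classes = coefs.shape[0] + 1
    logits = np.zeros((n, n_classes))
    design = np.column_stack([np.ones(n), x])
    non_ref = [k for k in range(n_classes) if k != ref]
    for row, k in enumerate(non_ref):
        logits[:, k] = design @ coefs[row]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def calibrate_class_intercepts(
    config: SimConfig,
    target_shares: np.ndarray,
    n_mc: int = 20000,
    n_iter: int = 60,
) -> SimConfig:
    """Solve the non-reference logit intercepts so that the marginal class
    shares under the covariate distribution match ``target_shares``.

    Iterative proportional adjustment on a fixed Monte-Carlo covariate
    sample (deterministic given the config seed).
    """
    target = np.asarray(target_shares, float)
    if len(target) != config.n_classes:
        raise ValueError("one target share per class required")
    target = target / target.sum()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    cov = _draw_covariates(rng, n_mc)
    x = _covariate_design(cov)
    coefs = config.class_logit_coefficients.copy()
    non_ref = [k for k in range(config.n_classes) if k != config.reference_class]
    for _ in range(n_iter):
        shares = _class_probs(coefs, config.reference_class, x).mean(axis=0)
        coefs[:, 0] += np.log(target[non_ref] / shares[non_ref]) - np.log(
            target[config.reference_class] / shares[config.reference_class]
        )
    return replace(config, class_logit_coefficients=coefs)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 50.0, 105.0)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": np.round(age, 1),
            "sex": (rng.random(n) < _FEMALE_RATE).astype(float),
            "education": rng.choice(
                np.arange(1, 9), size=n, p=np.asarray(_EDU_PROBS) / sum(_EDU_PROBS)
            ).astype(float),
            "non_active": (rng.random(n) < _NON_ACTIVE_RATE).astype(float),
            "never_smoker": (rng.random(n) < _NEVER_SMOKER_RATE).astype(float),
            "non_drinker": (rng.random(n) < _NON_DRINKER_RATE).astype(float),
        }
    )


def _item_wave_design(
    rng: np.random.Generator, config: SimConfig
) -> np.ndarray:
    """Boolean (items x waves) administration design: anchor items in every
    wave, each extra item in a random subset of >= 2 waves."""
    n_items = config.n_anchor_items + config.n_extra_items
    design = np.zeros((n_items, config.n_waves), dtype=bool)
    design[: config.n_anchor_items] = True
    for i in range(config.n_anchor_items, n_items):
        k = rng.integers(2, config.n_waves + 1)
        waves = rng.choice(config.n_waves, size=k, replace=False)
        design[i, waves] = True
    return design


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a complete cohort and then apply the configured missingness."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, J = config.n_persons, config.n_waves
    n_items = config.n_anchor_items + config.n_extra_items

    cov = _draw_covariates(rng, n)
    x = _covariate_design(cov)

    if config.n_classes > 1:
        probs = _class_probs(config.class_logit_coefficients, config.reference_class, x)
        u = rng.random(n)
        classes = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    else:
        classes = np.zeros(n, dtype=int)

    gamma = config.covariate_effects_per_class[classes]  # (n, 2, q)
    means = config.growth_means_per_class[classes] + np.einsum("nfq,nq->nf", gamma, x)
    chol = np.linalg.cholesky(config.growth_covariance)
    eta = means + rng.standard_normal((n, 2)) @ chol.T  # (I_p, S_p)

    lam = config.basis_loadings
    resid = rng.standard_normal((n, J)) * config.residual_sd_per_wave
    health = eta[:, [0]] + np.outer(eta[:, 1], lam) + resid  # (n, J)
    theta = (health - config.theta_center) / config.theta_scale

    # wave-varying item parameters
    b_i = config.item_difficulty_means
    a_i = config.item_discrimination_means
    sd_b = np.broadcast_to(np.asarray(config.difficulty_wave_sd, float), (n_items,))
    sd_a = np.broadcast_to(
        np.asarray(config.discrimination_wave_sd, float), (n_items,)
    )
    b_ij = b_i[:, None] + rng.standard_normal((n_items, J)) * sd_b[:, None]
    a_ij = a_i[:, None] + rng.standard_normal((n_items, J)) * sd_a[:, None]
    a_ij = np.abs(a_ij)  # enforce positivity (reflection; SDs are small)
    a_ij[a_ij < 1e-3] = 1e-3

    design = _item_wave_design(rng, config)
    b_ij[~design] = np.nan
    a_ij[~design] = np.nan

    # responses: Bernoulli(Phi(a*theta - b)) at administered item-waves
    p = ndtr(a_ij[None] * theta[:, None, :] - b_ij[None])  # (n, items, waves)
    y = (rng.random(p.shape) < p).astype(float)
    y[:, ~design] = np.nan

    dead = rng.random(n) < config.distal_death_prob_per_class[classes]
    # wave from which a deceased person is absent; J+1 = died after last wave.
    # Frailer people die sooner: per interval the deceased "survive to the
    # next wave" with probability expit(s0 + s1*theta_baseline).
    s0, s1 = config.death_timing
    death_wave = np.full(n, J + 2)
    q_next = expit(s0 + s1 * theta[:, 0])
    dw = np.full(n, 2)
    alive_past = dead.copy()
    for w in range(2, J + 2):
        surv = alive_past & (rng.random(n) < q_next)
        dw[surv] = w + 1
        alive_past = surv
    death_wave[dead] = np.minimum(dw[dead], J + 1)

    # covariate item-level missingness
    if config.covariate_missing_rate > 0:
        for col in ["age", "sex", "education", "non_active", "never_smoker", "non_drinker"]:
            miss = rng.random(n) < config.covariate_missing_rate
            cov.loc[miss, col] = np.nan

    truth = {
        "theta": theta,
        "health_score": health,
        "class_labels": classes + 1,
        "growth_factors": eta,
        "item_difficulty": b_i,
        "item_discrimination": a_i,
        "item_difficulty_wave": b_ij,
        "item_discrimination_wave": a_ij,
        "item_wave_design": design,
        "death_wave": death_wave,
        "present": np.ones((n, J), dtype=bool),
        "response_cube": y,  # (n, items, waves), NaN where not administered
    }
    mortality = pd.DataFrame({"person_id": np.arange(n), "dead": dead.astype(float)})
    cohort = SyntheticCohort(
        responses=pd.DataFrame(
            columns=["person_id", "wave", "item_id", "response"]
        ),  # filled by impose_missingness
        covariates=cov,
        mortality=mortality,
        truth=truth,
        config=config,
    )
    return impose_missingness(cohort, config)


def _cube_to_long(y: np.ndarray) -> pd.DataFrame:
    pid, item, wave = np.nonzero(~np.isnan(y))
    return pd.DataFrame(
        {
            "person_id": pid,
            "wave": wave + 1,
            "item_id": item,
            "response": y[pid, item, wave].astype(np.int8),
        }
    )


def impose_missingness(cohort: SyntheticCohort, config: SimConfig) -> SyntheticCohort:
    """Apply death truncation, MAR attrition and administrative missingness.

    Attrition is a monotone logistic hazard on the previous wave's observed
    health score (standardised), making the missing-at-random assumption
    concrete. With ``attrition_hazard=None`` neither dropout nor death
    truncation is applied and the panel is returned unchanged apart from
    administrative missingness.
    """
    if not 0 <= config.admin_missing_rate <= 1:
        raise ValueError("admin_missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    y = cohort.truth["response_cube"].copy()
    n, n_items, J = y.shape
    present = np.ones((n, J), dtype=bool)

    if config.attrition_hazard is not None:
        c0, c1 = config.attrition_hazard
        theta = cohort.truth["theta"]
        death_wave = cohort.truth["death_wave"]
        out = np.zeros(n, dtype=bool)
        for j in range(1, J):
            hazard = expit(c0 + c1 * theta[:, j - 1])
            out |= rng.random(n) < hazard
            present[:, j] = ~out & (death_wave > j + 1)
        present[:, 0] = True
        y[np.broadcast_to(~present[:, None, :], y.shape)] = np.nan

    if config.admin_missing_rate > 0:
        admin = rng.random(y.shape) < config.admin_missing_rate
        y[admin] = np.nan

    truth = dict(cohort.truth)
    truth["present"] = present
    truth["response_cube_observed"] = y
    return SyntheticCohort(
        responses=_cube_to_long(y),
        covariates=cohort.covariates,
        mortality=cohort.mortality,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# raw-answer recoding

_RECODE_MAP = {
    "yes": 1,
    "no": 0,
    "cannot_do": 1,  # "cannot do the activity" counts as having the difficulty
    "do_not_do": 0,  # "do not do the activity" counts as not having it
    "refused": None,
    "declined": None,
}


def apply_recoding(
    raw_panel: pd.DataFrame, adverse_items: set | None = None
) -> pd.DataFrame:
    """Recode categorical answers to binary difficulty indicators.

    ``raw_panel`` needs columns person_id, wave, item_id, answer. Items
    listed in ``adverse_items`` are reverse-coded after mapping (their
    'yes' means *absence* of the difficulty).
    """
    adverse_items = adverse_items or set()
    answers = raw_panel["answer"]
    unknown = set(answers.dropna()) - set(_RECODE_MAP)
    if unknown:
        raise ValueError(f"unknown answer categories: {sorted(unknown)}")
    coded = answers.map(lambda v: _RECODE_MAP.get(v) if isinstance(v, str) else None)
    out = raw_panel[["person_id", "wave", "item_id"]].copy()
    out["response"] = pd.array(coded, dtype="Int64")
    flip = out["item_id"].isin(adverse_items) & out["response"].notna()
    out.loc[flip, "response"] = 1 - out.loc[flip, "response"]
    return out


def dichotomize_fluency(animal_counts) -> np.ndarray:
    """Flag low verbal fluency: counts at or below the empirical 25th
    percentile (linear-interpolation quantile) are coded 1; missing values
    propagate."""
    counts = np.asarray(animal_counts, dtype=float)
    observed = counts[~np.isnan(counts)]
    if observed.size == 0:
        raise ValueError("all fluency counts missing")
    q25 = np.quantile(observed, 0.25)  # linear interpolation rule
    out = np.where(counts <= q25, 1.0, 0.0)
    out[np.isnan(counts)] = np.nan
    return out


# ---------------------------------------------------------------------------
# CSV interfaces

def write_cohort_csv(cohort: SyntheticCohort, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out / "panel.csv",
        "covariates": out / "covariates.csv",
        "mortality": out / "mortality.csv",
        "truth": out / "truth.json",
    }
    cohort.responses.to_csv(paths["panel"], index=False)
    cohort.covariates.to_csv(paths["covariates"], index=False)
    cohort.mortality.to_csv(paths["mortality"], index=False)
    truth_small = {
        "class_labels": cohort.truth["class_labels"].tolist(),
        "item_difficulty": cohort.truth["item_difficulty"].tolist(),
        "item_discrimination": cohort.truth["item_discrimination"].tolist(),
        "growth_factors": cohort.truth["growth_factors"].tolist(),
        "seed": cohort.config.seed,
    }
    paths["truth"].write_text(json.dumps(truth_small))
    return {k: str(v) for k, v in paths.items()}


def read_panel_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"person_id", "wave", "item_id", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    return df
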