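import warnings

import numpy as np
import pandas as pd
import pytest

from healthtraj.simulate import (
    COVARIATE_COLUMNS,
    covariate_design_frame,
    default_config,
    generate_cohort,
)

warnings.filterwarnings("ignore", category=RuntimeWarning, module="healthtraj")


@pytest.fixture(scope="session")
def cohort10k():
    """A study-condition cohort large enough for moment checks."""
    return generate_cohort(default_config(10000, seed=1234))


@pytest.fixture(scope="session")
def clean_cohort():
    """No attrition / no administrative missingness: complete panel."""
    cfg = default_config(
        300, seed=11, admin_missing_rate=0.0, attrition_hazard=None
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def irt_fit_small(clean_cohort):
    """Variant-3 fit on the clean cohort, shared across IRT tests."""
    from healthtraj.irt import HealthIRTModel

    model = HealthIRTModel(clean_cohort.responses, variant=3)
    return model.fit(n_iterations=600, n_burnin=100, n_chains=2, seed=5)


@pytest.fixture(scope="session")
def gmm_inputs_small():
    """An 800-person two-class cohort with design matrix, for GMM tests."""
    cfg = default_config(
        800,
        seed=31,
        n_classes=2,
        growth_means_per_class=np.array([[72.0, -12.0], [45.0, -6.0]]),
        distal_death_prob_per_class=np.array([0.1, 0.8]),
        class_logit_coefficients=np.array([[-1.5, 0.8, -0.3, 0.2, 0.0, 0.3, 0.0]]),
        reference_class=0,
    )
    coh = generate_cohort(cfg)
    design = covariate_design_frame(coh.covariates)
    return coh, coh.observed_scores(), design


@pytest.fixture(scope="session")
def toy_mixture_data():
    """Five persons, four waves with holes, for exact-oracle comparisons."""
    rng = np.random.default_rng(0)
    scores = pd.DataFrame(
        {
            "person_id": [1, 1, 1, 1, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4, 5, 5, 5],
            "wave": [1, 2, 3, 4, 1, 2, 4, 1, 2, 3, 4, 1, 2, 3, 4, 1, 3, 4],
            "score": rng.normal(60, 10, 18),
        }
    )
    mortality = pd.DataFrame(
        {"person_id": [1, 2, 3, 4, 5], "dead": [1, 0, np.nan, 1, 0]}
    )
    covariates = pd.DataFrame({"person_id": [1, 2, 3, 4, 5], "z": [0.5, -1, 0, 2, 1]})
    return scores, covariates, mortality
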