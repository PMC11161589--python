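import logging

import numpy as np
import pytest

from liferisk.synthetic_cohort import GeneratorConfig

# unfit-cell / unavailable-transition warnings are expected noise in tests
logging.getLogger("liferisk").setLevel(logging.ERROR)


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


#: generating model used by several suites: constant annual probabilities
BASE_COEFFS = {
    ("Health", "Ht"): {"intercept": logit(0.01)},
    ("Health", "HyperLip"): {"intercept": logit(0.01)},
    ("Health", "Dm"): {"intercept": logit(0.01)},
    ("Health", "CAD"): {"intercept": logit(0.005)},
    ("Health", "Death"): {"intercept": logit(0.003)},
    ("Ht", "Ht&HyperLip"): {"intercept": logit(0.02)},
    ("Ht", "CAD"): {"intercept": logit(0.008)},
    ("Ht", "Death"): {"intercept": logit(0.004)},
}


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-person cohort shared across suites (session-scoped for speed)."""
    from liferisk.synthetic_cohort import simulate_cohort

    cfg = GeneratorConfig(
        n_persons=2000, seed=42, coefficients=dict(BASE_COEFFS), censor_lo=70, censor_hi=90
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_smoothed_table(small_cohort):
    """Fitted + smoothed table for the shared small cohort."""
    from liferisk.coefficient_smoothing import SmootherConfig, smooth_table
    from liferisk.ehr_timeline import expand_cohort
    from liferisk.transition_fitting import fit_all

    _, records = small_cohort
    py = expand_cohort(records)
    raw = fit_all(py, covariates=())
    return smooth_table(raw, SmootherConfig())
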