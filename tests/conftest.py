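import logging

import numpy as np
import pytest
from hypothesis import settings

from kidlb import (
    GeneratorConfig,
    TrueEffects,
    apply_det_concordance_filter,
    generate_cohort,
    null_effects,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# silence per-fit warnings in test output; failures still surface via asserts
logging.getLogger("kidlb").setLevel(logging.ERROR)


def zero_fn(x):
    return np.zeros_like(np.asarray(x, dtype=float))


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed SET/DET cohort (default scenario), concordance-filtered."""
    cfg = GeneratorConfig(n_cycles=150, seed=11)
    cycles, embryos = generate_cohort(cfg)
    return apply_det_concordance_filter(cycles, embryos)


@pytest.fixture(scope="session")
def set_cohort():
    """SET-only cohort: the embryo-level model is exactly the generative law."""
    cfg = GeneratorConfig(n_cycles=400, set_fraction=1.0, seed=23)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no covariate effects: outcome is Bernoulli(0.2) iid."""
    from scipy.special import logit

    cfg = GeneratorConfig(
        n_cycles=400,
        set_fraction=1.0,
        seed=37,
        true_effects=null_effects(float(logit(0.2))),
        random_intercept_sd=0.0,
    )
    return generate_cohort(cfg)
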