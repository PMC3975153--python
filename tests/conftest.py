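import numpy as np
import pytest
from hypothesis import settings

from intersamm import (
    CauseCategory,
    CauseRegistry,
    Indicator,
    IndicatorRegistry,
    PriorMatrix,
    default_matrix,
    separable_matrix,
)
from intersamm.model_registry import RESERVED_CAUSE_CODES

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matrix72():
    """The packaged 72x10 illustrative matrix."""
    return default_matrix()


@pytest.fixture(scope="session")
def sep_matrix():
    """Well-separated 5-cause synthetic matrix for simulation studies."""
    return separable_matrix()


def make_matrix(conditional, prior_cause, prior_samm=0.1, baseline=None,
                cond_samm=None):
    """Small hand-specified PriorMatrix for unit tests.

    conditional: (n_ind, n_causes) array of P(I|C).  P(I|SAMM) defaults to
    the cause-prior-weighted mixture and P(I) to the coherent total-
    probability reconstruction with baseline-negative 0.05.
    """
    conditional = np.asarray(conditional, dtype=float)
    prior_cause = np.asarray(prior_cause, dtype=float)
    n_ind, n_causes = conditional.shape
    indicators = IndicatorRegistry(
        Indicator(f"i{k + 1}", f"indicator {k + 1}", k + 1)
        for k in range(n_ind)
    )
    causes = CauseRegistry(
        [CauseCategory(f"c{k + 1}", f"cause {k + 1}") for k in range(n_causes)]
        + [CauseCategory(code, code, kind="reserved")
           for code in RESERVED_CAUSE_CODES]
    )
    if cond_samm is None:
        w = prior_cause / prior_cause.sum()
        cond_samm = conditional @ w
    cond_samm = np.asarray(cond_samm, dtype=float)
    if baseline is None:
        baseline = cond_samm * prior_samm + 0.05 * (1.0 - prior_samm)
    return PriorMatrix(
        indicators=indicators,
        causes=causes,
        prior_samm=prior_samm,
        prior_cause=prior_cause,
        baseline_indicator=np.asarray(baseline, dtype=float),
        conditional=conditional,
        conditional_samm=cond_samm,
    )


def random_matrix(rng, n_ind, n_causes, prior_samm=None):
    """Random valid matrix for property/oracle tests."""
    conditional = rng.uniform(0.05, 0.9, size=(n_ind, n_causes))
    prior_cause = rng.uniform(0.01, 0.8 / n_causes, size=n_causes)
    prior_samm = prior_samm if prior_samm is not None else rng.uniform(0.05, 0.5)
    cond_samm = rng.uniform(0.05, 0.9, size=n_ind)
    # choose P(I) coherent with a baseline-negative drawn in (0.05, 0.9)
    p_not = rng.uniform(0.05, 0.9, size=n_ind)
    baseline = cond_samm * prior_samm + p_not * (1.0 - prior_samm)
    return make_matrix(conditional, prior_cause, prior_samm=prior_samm,
                       baseline=baseline, cond_samm=cond_samm)
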