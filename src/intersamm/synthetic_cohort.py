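"""Synthetic cohorts with known ground truth under a reporting-noise model.

Women's recall of pregnancy and delivery events is noisy and unspecific,
so any evaluation of a symptom-based probabilistic classifier needs
cohorts whose true morbidity status, cause and latent symptoms are known.
The generator draws, per case:

1. a true status from (uncomplicated, morbid non-SAMM, SAMM) prevalences;
2. for morbid cases, a single true cause from a configurable CSMF;
3. latent indicator presence — Bernoulli(P(I|C)) under the generating
   matrix for morbid cases, Bernoulli(P(I|¬SAMM)) for uncomplicated ones;
4. the observed response, passing latent presence through independent
   per-indicator misclassification: a present indicator is reported with
   probability ``report_sensitivity``, an absent one with probability
   ``report_false_positive``.

Everything is reproducible from a single seeded generator.  The module
also provides log-odds jitter of a matrix's conditional probabilities,
used to probe robustness of population estimates to misspecified priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .bayes_engine import NO, YES, CaseRecord
from .model_registry import (
    EPS,
    CauseCategory,
    CauseRegistry,
    Indicator,
    IndicatorRegistry,
    InterSAMMError,
    PriorMatrix,
    RESERVED_CAUSE_CODES,
    baseline_negative_vector,
)

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "TruthRecord",
    "simulate_cohort",
    "perturb_matrix",
    "separable_matrix",
]


class ConfigError(InterSAMMError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated case."""

    case_id: str
    true_status: str
    true_cause: str | None
    latent: tuple[int, ...]  # per-indicator latent presence flags


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the hospital-based development case-mix: roughly two
    uncomplicated deliveries per complicated one, every complicated case at
    the severe end of the spectrum, imperfect recall (sensitivity 0.9) and
    a small per-indicator false-reporting rate (0.02) that over 25–72
    indicators yields the ~1 spurious affirmative per uncomplicated woman
    seen in practice.
    """

    generating_matrix: PriorMatrix
    n_cases: int = 1000
    prevalence_samm: float = 0.33
    prevalence_morbid_non_samm: float = 0.0
    true_csmf: Mapping[str, float] | None = None  # default: normalized priors
    report_sensitivity: float = 0.9
    report_false_positive: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError("n_cases must be positive")
        for name in ("prevalence_samm", "prevalence_morbid_non_samm",
                     "report_sensitivity", "report_false_positive"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if self.prevalence_samm + self.prevalence_morbid_non_samm > 1.0:
            raise ConfigError("morbidity prevalences sum above 1")
        if self.true_csmf is not None:
            codes = self.generating_matrix.causes.codes
            unknown = [c for c in self.true_csmf if c not in codes]
            if unknown:
                raise ConfigError(f"true_csmf names unknown causes: {unknown}")
            total = float(sum(self.true_csmf.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"true_csmf must sum to 1, got {total}")
            if any(v < 0 for v in self.true_csmf.values()):
                raise ConfigError("true_csmf values must be nonnegative")

    def csmf_vector(self) -> np.ndarray:
        codes = self.generating_matrix.causes.codes
        if self.true_csmf is None:
            return self.generating_matrix.normalized_cause_prior()
        return np.array([self.true_csmf.get(c, 0.0) for c in codes])


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[list[CaseRecord], list[TruthRecord]]:
    """Draw a cohort of observed responses plus its ground truth."""
    matrix = config.generating_matrix
    rng = np.random.default_rng(config.seed)
    codes = matrix.indicators.codes
    cause_codes = matrix.causes.codes
    n_ind = matrix.n_indicators

    p_status = np.array([
        1.0 - config.prevalence_samm - config.prevalence_morbid_non_samm,
        config.prevalence_morbid_non_samm,
        config.prevalence_samm,
    ])
    statuses = rng.choice(
        ["uncomplicated", "morbid_non_samm", "samm"],
        size=config.n_cases, p=p_status,
    )
    csmf = config.csmf_vector()
    p_not = baseline_negative_vector(matrix)

    pad = len(str(config.n_cases))
    cases: list[CaseRecord] = []
    truths: list[TruthRecord] = []
    for k in range(config.n_cases):
        status = str(statuses[k])
        if status == "uncomplicated":
            cause: str | None = None
            p_latent = p_not
        else:
            c = int(rng.choice(len(cause_codes), p=csmf))
            cause = cause_codes[c]
            p_latent = matrix.conditional[:, c]
        latent = rng.random(n_ind) < p_latent
        p_report = np.where(latent, config.report_sensitivity,
                            config.report_false_positive)
        observed = rng.random(n_ind) < p_report
        case_id = f"sim{k + 1:0{pad}d}"
        cases.append(CaseRecord(
            case_id=case_id,
            responses={code: (YES if observed[i] else NO)
                       for i, code in enumerate(codes)},
        ))
        truths.append(TruthRecord(
            case_id=case_id,
            true_status=status,
            true_cause=cause,
            latent=tuple(int(x) for x in latent),
        ))
    return cases, truths


def perturb_matrix(matrix: PriorMatrix, log_odds_sd: float,
                   seed: int = 0) -> PriorMatrix:
    """Jitter conditional probabilities on the log-odds scale.

    Each P(I|C) and P(I|SAMM) entry becomes expit(logit(p) + sd·z) with
    z ~ Normal(0,1).  The z draws depend only on the seed, so for a fixed
    seed the perturbation grows continuously with ``log_odds_sd`` — a grid
    of sd values probes robustness with a common noise realization.
    """
    if log_odds_sd < 0:
        raise ConfigError("log_odds_sd must be nonnegative")
    if log_odds_sd == 0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    z_cond = rng.standard_normal(matrix.conditional.shape)
    z_samm = rng.standard_normal(matrix.conditional_samm.shape)

    def jitter(p: np.ndarray, z: np.ndarray) -> np.ndarray:
        logit = np.log(p) - np.log1p(-p)
        out = 1.0 / (1.0 + np.exp(-(logit + log_odds_sd * z)))
        return np.clip(out, EPS, 1.0 - EPS)

    return replace(
        matrix.copy(),
        conditional=jitter(matrix.conditional, z_cond),
        conditional_samm=jitter(matrix.conditional_samm, z_samm),
    )


def separable_matrix(cause_codes: Sequence[str] = ("c1", "c2", "c3", "c4", "c5"),
                     signatures_per_cause: int = 5,
                     n_filler: int = 5,
                     signature_p: float = 0.8,
                     baseline: float = 0.02,
                     prior_samm: float = 0.05,
                     cause_prior: float = 0.02) -> PriorMatrix:
    """A synthetic matrix with disjoint signature indicators per cause.

    Each cause gets ``signatures_per_cause`` indicators reported with
    probability ``signature_p`` under that cause and ``baseline``
    otherwise; filler indicators are cause-neutral.  P(I|SAMM) is the
    cause-prior-weighted mixture of P(I|C) and P(I) is rebuilt by total
    probability, so the matrix is internally coherent.  Used as a
    known-truth generating model in simulation studies.
    """
    nc = len(cause_codes)
    n_ind = nc * signatures_per_cause + n_filler
    indicators = []
    conditional = np.full((n_ind, nc), baseline)
    i = 0
    for c, code in enumerate(cause_codes):
        for s in range(signatures_per_cause):
            indicators.append(Indicator(f"sig_{code}_{s + 1}",
                                        f"signature {s + 1} of {code}", i + 1))
            conditional[i, c] = signature_p
            i += 1
    for f in range(n_filler):
        indicators.append(Indicator(f"filler_{f + 1}", f"filler {f + 1}", i + 1))
        i += 1

    prior_cause = np.full(nc, cause_prior)
    weights = prior_cause / prior_cause.sum()
    cond_samm = conditional @ weights
    p_i = cond_samm * prior_samm + baseline * (1.0 - prior_samm)
    causes = CauseRegistry(
        [CauseCategory(code, code) for code in cause_codes]
        + [CauseCategory(code, code, kind="reserved")
           for code in RESERVED_CAUSE_CODES]
    )
    return PriorMatrix(
        indicators=IndicatorRegistry(indicators),
        causes=causes,
        prior_samm=prior_samm,
        prior_cause=prior_cause,
        baseline_indicator=p_i,
        conditional=conditional,
        conditional_samm=cond_samm,
    )
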