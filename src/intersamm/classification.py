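"""Categorical classification of posterior profiles.

The continuous posterior likelihoods are converted into the categorical
outputs used for population reporting:

* morbidity status — below a 30% likelihood of severe morbidity a case is
  treated as uncomplicated (cause probabilities are zeroed); above 90% it
  is a severe near-miss (SAMM); in between it is morbid but not near-miss;
* determinate causes — a cause is reportable only if its posterior
  likelihood reached the square root of its unconditional prior, i.e. it
  must have risen decisively above its baseline (√p > p for p < 1);
* multiple causes — causes are reported most-likely first, and each
  additional cause must fall within 50% of the previously kept one.

A morbid case for which no cause clears the determinacy threshold is
"indeterminate".  The 1 − Σ(assigned likelihoods) remainder of a
cause-assigned case is its cause-uncertainty mass, carried forward into
population aggregation rather than discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .bayes_engine import PosteriorProfile
from .model_registry import InterSAMMError, PriorMatrix

__all__ = [
    "UNCOMPLICATED",
    "MORBID_NON_SAMM",
    "SAMM",
    "STATUSES",
    "RuleConfig",
    "CaseClassification",
    "classify_status",
    "determinate_causes",
    "select_multiple_causes",
    "classify_case",
    "classify_cohort",
    "write_classifications",
]

UNCOMPLICATED = "uncomplicated"
MORBID_NON_SAMM = "morbid_non_samm"
SAMM = "samm"
STATUSES = (UNCOMPLICATED, MORBID_NON_SAMM, SAMM)


@dataclass(frozen=True)
class RuleConfig:
    """Tunable classification rules.

    low_cut / high_cut: morbidity-likelihood cutoffs (defaults 0.30/0.90;
    both boundaries inclusive to the middle band, since "below 30%" and
    "in excess of 90%" are strict).
    determinacy_rule: "to_sqrt" (posterior ≥ √prior, default) or "by_sqrt"
    (posterior ≥ prior + √prior; unsatisfiable for priors above ~0.38 and
    kept only as a sensitivity switch).
    chain_reference: whether the 50% multi-cause rule compares each cause
    to the "previous_kept" cause (default) or always to the "top" cause.
    """

    low_cut: float = 0.30
    high_cut: float = 0.90
    determinacy_rule: str = "to_sqrt"
    chain_reference: str = "previous_kept"

    def __post_init__(self) -> None:
        if not (0.0 < self.low_cut < self.high_cut < 1.0):
            raise InterSAMMError(
                f"cutoffs must satisfy 0 < low < high < 1, got "
                f"({self.low_cut}, {self.high_cut})"
            )
        if self.determinacy_rule not in ("to_sqrt", "by_sqrt"):
            raise InterSAMMError(
                f"unknown determinacy_rule {self.determinacy_rule!r}"
            )
        if self.chain_reference not in ("previous_kept", "top"):
            raise InterSAMMError(
                f"unknown chain_reference {self.chain_reference!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        known = {"low_cut", "high_cut", "determinacy_rule", "chain_reference"}
        unknown = set(data) - known
        if unknown:
            raise InterSAMMError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class CaseClassification:
    """Categorical outcome for one case."""

    case_id: str
    status: str
    assigned_causes: list[tuple[str, float]]  # (cause code, likelihood), desc.
    uncertainty_fraction: float
    indeterminate: bool

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise InterSAMMError(f"unknown status {self.status!r}")


def classify_status(p_samm: float, low_cut: float = 0.30,
                    high_cut: float = 0.90) -> str:
    """Map a morbidity likelihood onto the three-level status scale."""
    if not (0.0 <= p_samm <= 1.0):
        raise InterSAMMError(f"p_samm must lie in [0,1], got {p_samm}")
    if not (0.0 < low_cut < high_cut < 1.0):
        raise InterSAMMError("cutoffs must satisfy 0 < low < high < 1")
    if p_samm < low_cut:
        return UNCOMPLICATED
    if p_samm > high_cut:
        return SAMM
    return MORBID_NON_SAMM


def determinate_causes(profile: PosteriorProfile, matrix: PriorMatrix,
                       rule: str = "to_sqrt") -> list[tuple[str, float]]:
    """Causes whose posterior rose decisively above the unconditional prior.

    Under the default rule a cause is determinate iff its posterior
    likelihood ≥ √P(C).  Returned sorted by likelihood descending, ties
    broken by registry order; an empty list means the case is indeterminate.
    """
    out = []
    for c, code in enumerate(profile.cause_codes):
        prior = matrix.prior_cause[matrix.causes.position(code)]
        if rule == "to_sqrt":
            threshold = prior ** 0.5
        elif rule == "by_sqrt":
            threshold = prior + prior ** 0.5
        else:
            raise InterSAMMError(f"unknown determinacy rule {rule!r}")
        likelihood = float(profile.p_cause[c])
        if likelihood >= threshold:
            out.append((code, likelihood, c))
    # registry position as secondary key makes equal likelihoods deterministic
    out.sort(key=lambda t: (-t[1], t[2]))
    return [(code, lik) for code, lik, _ in out]


def select_multiple_causes(determinate: Sequence[tuple[str, float]],
                           chain_reference: str = "previous_kept",
                           ) -> list[tuple[str, float]]:
    """Apply the 50% rule to a descending-sorted determinate-cause list.

    The top cause is always kept; each subsequent cause is kept iff its
    likelihood is at least half of the reference (the previously kept
    cause, or the top cause), stopping at the first failure so the output
    is a prefix of the input.
    """
    if not determinate:
        return []
    kept = [tuple(determinate[0])]
    for code, lik in determinate[1:]:
        ref = kept[-1][1] if chain_reference == "previous_kept" else kept[0][1]
        if lik >= 0.5 * ref:
            kept.append((code, lik))
        else:
            break
    return kept


def classify_case(profile: PosteriorProfile, matrix: PriorMatrix,
                  config: RuleConfig | None = None) -> CaseClassification:
    """Full rule pipeline: status, then determinacy, then the 50% rule."""
    config = config or RuleConfig()
    status = classify_status(profile.p_samm, config.low_cut, config.high_cut)
    if status == UNCOMPLICATED:
        return CaseClassification(
            case_id=profile.case_id,
            status=status,
            assigned_causes=[],
            uncertainty_fraction=0.0,
            indeterminate=False,
        )
    determinate = determinate_causes(profile, matrix, config.determinacy_rule)
    assigned = select_multiple_causes(determinate, config.chain_reference)
    if not assigned:
        return CaseClassification(
            case_id=profile.case_id,
            status=status,
            assigned_causes=[],
            uncertainty_fraction=0.0,
            indeterminate=True,
        )
    total = sum(lik for _, lik in assigned)
    return CaseClassification(
        case_id=profile.case_id,
        status=status,
        assigned_causes=assigned,
        uncertainty_fraction=1.0 - total,
        indeterminate=False,
    )


def classify_cohort(profiles: Iterable[PosteriorProfile], matrix: PriorMatrix,
                    config: RuleConfig | None = None) -> list[CaseClassification]:
    return [classify_case(p, matrix, config) for p in profiles]


def write_classifications(classifications: Sequence[CaseClassification],
                          path: str | Path) -> None:
    """Classification CSV: status, indeterminate flag, cause/likelihood pairs."""
    if not classifications:
        raise InterSAMMError("no classifications to write")
    k = max((len(c.assigned_causes) for c in classifications), default=0)
    rows = []
    for c in classifications:
        row: dict[str, object] = {
            "case_id": c.case_id,
            "status": c.status,
            "indeterminate": int(c.indeterminate),
            "uncertainty_fraction": c.uncertainty_fraction,
        }
        for j in range(k):
            if j < len(c.assigned_causes):
                code, lik = c.assigned_causes[j]
            else:
                code, lik = "", ""
            row[f"cause_{j + 1}"] = code
            row[f"likelihood_{j + 1}"] = lik
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
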