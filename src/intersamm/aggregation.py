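"""Population aggregation: fractional case-splitting and CSMFs.

Each classified morbid case contributes its unit mass fractionally: the
likelihood of each assigned cause goes to that cause's population count
and the remainder (1 − Σ likelihoods) to the cause-uncertainty count.  A
case assigned haemorrhage at 0.50 and anaemia at 0.40 therefore adds 0.5,
0.4 and 0.1 to the haemorrhage, anaemia and uncertainty counts.  Dividing
the counts by the number of cases yields cause-specific morbidity
fractions (CSMFs) together with explicit uncomplicated, indeterminate and
uncertainty fractions, so the population table conserves mass exactly.

Two reporting scopes are supported: ``samm_only`` attributes causes only
for near-miss (>90%) cases, with other morbid cases reported in a
separate non-scope bucket; ``all_morbid`` attributes causes for every
case above the 30% morbidity cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import (
    MORBID_NON_SAMM,
    SAMM,
    STATUSES,
    UNCOMPLICATED,
    CaseClassification,
)
from .model_registry import InterSAMMError

__all__ = [
    "SAMM_ONLY",
    "ALL_MORBID",
    "EmptyCohortError",
    "PopulationSummary",
    "split_case",
    "summarize",
]

SAMM_ONLY = "samm_only"
ALL_MORBID = "all_morbid"
UNCERTAINTY = "uncertainty"


class EmptyCohortError(InterSAMMError):
    """Aggregation over zero cases is undefined."""


@dataclass
class PopulationSummary:
    """Population-level morbidity-status distribution and CSMFs.

    All quantities are fractions of ``n_cases``.  Mass conservation:
    uncomplicated + non_scope + indeterminate + uncertainty + other
    + Σ csmf = 1 (non_scope is only populated under samm_only scope;
    other only by clinician-reference summaries).
    """

    n_cases: int
    status_fractions: dict[str, float]
    csmf: dict[str, float]
    uncomplicated_fraction: float
    indeterminate_fraction: float
    uncertainty_fraction: float
    scope: str
    non_scope_fraction: float = 0.0
    other_fraction: float = 0.0

    @property
    def cause_codes(self) -> list[str]:
        return list(self.csmf)

    def determinate_csmf(self, normalize: bool = False) -> pd.Series:
        """CSMFs over the substantive causes, optionally renormalized to 1."""
        s = pd.Series(self.csmf, dtype=float)
        if normalize:
            total = s.sum()
            if total <= 0.0:
                raise InterSAMMError("no determinate cause mass to normalize")
            s = s / total
        return s

    def total_mass(self) -> float:
        return (
            self.uncomplicated_fraction
            + self.non_scope_fraction
            + self.indeterminate_fraction
            + self.uncertainty_fraction
            + self.other_fraction
            + sum(self.csmf.values())
        )

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "scope": self.scope,
            "status_fractions": dict(self.status_fractions),
            "csmf": dict(self.csmf),
            "uncomplicated_fraction": self.uncomplicated_fraction,
            "non_scope_fraction": self.non_scope_fraction,
            "indeterminate_fraction": self.indeterminate_fraction,
            "uncertainty_fraction": self.uncertainty_fraction,
            "other_fraction": self.other_fraction,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")

    def to_table(self, percent: bool = True, decimals: int = 1) -> pd.DataFrame:
        """Cause-rows table in the style of a population CSMF report."""
        rows = [("Non-scope morbid cases", self.non_scope_fraction),
                ("Uncomplicated", self.uncomplicated_fraction),
                ("Cause uncertainty", self.uncertainty_fraction)]
        rows += sorted(self.csmf.items(), key=lambda kv: -kv[1])
        rows += [("Other cause", self.other_fraction),
                 ("Indeterminate cause", self.indeterminate_fraction)]
        frame = pd.DataFrame(rows, columns=["category", "fraction"])
        if percent:
            frame["fraction"] = (100.0 * frame["fraction"]).round(decimals)
            frame = frame.rename(columns={"fraction": "percent"})
        return frame


def split_case(classification: CaseClassification) -> dict[str, float]:
    """Fractional population-count contributions of one cause-assigned case.

    Returns {cause code: likelihood, ..., "uncertainty": remainder}; the
    contributions sum to 1 by construction.
    """
    if not classification.assigned_causes:
        raise InterSAMMError(
            f"case {classification.case_id!r} has no assigned causes to split"
        )
    contributions = {code: float(lik)
                     for code, lik in classification.assigned_causes}
    contributions[UNCERTAINTY] = 1.0 - sum(contributions.values())
    return contributions


def summarize(classifications: Sequence[CaseClassification],
              scope: str = ALL_MORBID,
              cause_codes: Sequence[str] | None = None) -> PopulationSummary:
    """Aggregate case classifications into a population summary.

    Uncomplicated cases count toward the uncomplicated fraction; morbid
    cases outside the scope (non-SAMM morbid cases under ``samm_only``)
    count toward the non-scope bucket; in-scope indeterminate cases add
    their full unit mass to the indeterminate count; the rest are split
    fractionally between their assigned causes and cause uncertainty.
    """
    if scope not in (SAMM_ONLY, ALL_MORBID):
        raise InterSAMMError(f"unknown scope {scope!r}")
    if not classifications:
        raise EmptyCohortError("cannot summarize an empty cohort")
    n = len(classifications)

    if cause_codes is None:
        seen: list[str] = []
        for c in classifications:
            for code, _ in c.assigned_causes:
                if code not in seen:
                    seen.append(code)
        cause_codes = seen

    status_counts = {s: 0 for s in STATUSES}
    cause_counts = {code: 0.0 for code in cause_codes}
    uncomplicated = 0.0
    non_scope = 0.0
    indeterminate = 0.0
    uncertainty = 0.0

    in_scope_statuses = {SAMM} if scope == SAMM_ONLY else {SAMM, MORBID_NON_SAMM}
    for c in classifications:
        status_counts[c.status] += 1
        if c.status == UNCOMPLICATED:
            uncomplicated += 1.0
        elif c.status not in in_scope_statuses:
            non_scope += 1.0
        elif c.indeterminate:
            indeterminate += 1.0
        else:
            for code, mass in split_case(c).items():
                if code == UNCERTAINTY:
                    uncertainty += mass
                else:
                    if code not in cause_counts:
                        raise InterSAMMError(
                            f"case {c.case_id!r} assigned unknown cause {code!r}"
                        )
                    cause_counts[code] += mass

    return PopulationSummary(
        n_cases=n,
        status_fractions={s: status_counts[s] / n for s in STATUSES},
        csmf={code: cause_counts[code] / n for code in cause_codes},
        uncomplicated_fraction=uncomplicated / n,
        non_scope_fraction=non_scope / n,
        indeterminate_fraction=indeterminate / n,
        uncertainty_fraction=uncertainty / n,
        scope=scope,
    )
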