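"""Per-case Bayesian updating of morbidity and cause likelihoods.

Two tracks are maintained for every delivery, following the design of the
original program:

* the *all-cause track*: a two-hypothesis (severe morbidity vs not) odds
  update.  Each affirmative indicator multiplies the odds of severe acute
  maternal morbidity by the likelihood ratio P(I|SAMM)/P(I|¬SAMM);
* the *cause track*: a categorical posterior over the substantive cause
  categories, multiplied by P(I|C) per affirmative indicator and
  renormalized.

Indicators are assumed conditionally independent given the hypothesis;
"no" and "missing" responses carry no evidence (self-report absence is
uninformative).  Both tracks accumulate in log space so that cases with
many reported indicators cannot underflow, and affirmative indicators are
always processed in registry order, making the result — and even the
floating-point rounding — independent of the order responses were given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_registry import (
    DegeneratePriorError,
    IndicatorRegistry,
    InterSAMMError,
    PriorMatrix,
    SchemaError,
    baseline_negative_vector,
    derive_baseline_negative,
)

__all__ = [
    "YES",
    "NO",
    "MISSING",
    "UnderflowError",
    "CaseRecord",
    "TraceStep",
    "PosteriorProfile",
    "update_samm",
    "update_causes",
    "evaluate_case",
    "evaluate_cohort",
    "read_cohort",
    "write_posteriors",
    "write_trace",
]

YES = "yes"
NO = "no"
MISSING = "missing"
_RESPONSES = frozenset({YES, NO, MISSING})


class UnderflowError(InterSAMMError):
    """Every cause hypothesis received zero posterior mass."""


@dataclass(frozen=True)
class CaseRecord:
    """One delivery: a case id and a response per indicator.

    ``responses`` maps indicator code → {"yes","no","missing"}; codes not
    present are treated as missing.
    """

    case_id: str
    responses: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.responses.values()} - _RESPONSES
        if bad:
            raise SchemaError(
                f"case {self.case_id!r}: invalid responses {sorted(bad)}"
            )

    def affirmative(self, registry: IndicatorRegistry) -> list[str]:
        """Affirmative indicator codes, in registry order."""
        out = []
        for ind in registry:
            if self.responses.get(ind.code, MISSING) == YES:
                out.append(ind.code)
        return out


@dataclass(frozen=True)
class TraceStep:
    """State of both tracks after one indicator's update."""

    indicator: str
    p_samm: float
    p_cause: np.ndarray


@dataclass
class PosteriorProfile:
    """Posterior morbidity likelihood and cause distribution for one case."""

    case_id: str
    p_samm: float
    p_cause: np.ndarray        # over substantive causes, sums to 1
    cause_codes: list[str]
    n_positive: int
    trace: list[TraceStep] = field(default_factory=list)

    def cause_series(self) -> pd.Series:
        return pd.Series(self.p_cause, index=self.cause_codes)


def update_samm(p_current: float, indicator: str, matrix: PriorMatrix) -> float:
    """One affirmative-indicator update of the severe-morbidity likelihood.

    odds' = odds · P(I|SAMM)/P(I|¬SAMM); returns odds'/(1+odds').
    """
    if p_current <= 0.0 or p_current >= 1.0:
        raise DegeneratePriorError(
            f"cannot update an absorbing morbidity likelihood of {p_current}"
        )
    i = matrix.indicators.position(indicator)
    p_i_s = matrix.conditional_samm[i]
    p_i_not = derive_baseline_negative(matrix, i)
    odds = p_current / (1.0 - p_current) * (p_i_s / p_i_not)
    return odds / (1.0 + odds)


def update_causes(p_vector: Sequence[float], indicator: str,
                  matrix: PriorMatrix) -> np.ndarray:
    """One affirmative-indicator update of the cause distribution.

    p'_c ∝ p_c · P(I|C=c), renormalized over the substantive causes.
    """
    p = np.asarray(p_vector, dtype=float)
    i = matrix.indicators.position(indicator)
    updated = p * matrix.conditional[i, :]
    total = updated.sum()
    if total <= 0.0:
        raise UnderflowError(
            f"all cause hypotheses have zero mass after indicator {indicator!r}"
        )
    return updated / total


def evaluate_case(case: CaseRecord, matrix: PriorMatrix,
                  keep_trace: bool = True) -> PosteriorProfile:
    """Run both Bayesian tracks over a case's affirmative indicators.

    Starts from p_samm = P(SAMM) and p_cause ∝ P(C); each affirmative
    indicator (registry order) contributes one multiplicative update per
    track.  Negative and missing responses contribute nothing; a case with
    no affirmatives returns the priors unchanged.
    """
    if matrix.prior_samm <= 0.0 or matrix.prior_samm >= 1.0:
        raise DegeneratePriorError("P(SAMM) must lie strictly inside (0,1)")
    affirmative = case.affirmative(matrix.indicators)
    positions = [matrix.indicators.position(code) for code in affirmative]

    log_odds0 = np.log(matrix.prior_samm) - np.log1p(-matrix.prior_samm)
    p_not = baseline_negative_vector(matrix)
    log_lr = np.log(matrix.conditional_samm) - np.log(p_not)

    log_cause = np.log(matrix.normalized_cause_prior())
    log_cond = np.log(matrix.conditional)

    trace: list[TraceStep] = []
    log_odds = log_odds0
    log_c = log_cause.copy()
    for code, i in zip(affirmative, positions):
        log_odds = log_odds + log_lr[i]
        log_c = log_c + log_cond[i, :]
        if keep_trace:
            step_cause = np.exp(log_c - log_c.max())
            trace.append(TraceStep(
                indicator=code,
                p_samm=_expit(log_odds),
                p_cause=step_cause / step_cause.sum(),
            ))

    p_cause = np.exp(log_c - log_c.max())
    total = p_cause.sum()
    if not np.isfinite(total) or total <= 0.0:
        raise UnderflowError(f"case {case.case_id!r}: cause posterior underflow")
    return PosteriorProfile(
        case_id=case.case_id,
        p_samm=_expit(log_odds),
        p_cause=p_cause / total,
        cause_codes=list(matrix.causes.codes),
        n_positive=len(affirmative),
        trace=trace,
    )


def _expit(log_odds: float) -> float:
    if log_odds >= 0:
        return 1.0 / (1.0 + np.exp(-log_odds))
    e = np.exp(log_odds)
    return e / (1.0 + e)


def evaluate_cohort(cases: Iterable[CaseRecord], matrix: PriorMatrix,
                    keep_trace: bool = False) -> list[PosteriorProfile]:
    """Evaluate every case in a cohort."""
    return [evaluate_case(case, matrix, keep_trace=keep_trace) for case in cases]


# ---------------------------------------------------------------------------
# Cohort I/O
#
# Cohort CSV: header "case_id" plus indicator codes; cells 1/0/empty map to
# yes/no/missing.  Unknown columns are rejected unless ignore_unknown.
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, registry: IndicatorRegistry,
                ignore_unknown: bool = False) -> list[CaseRecord]:
    """Read a cohort CSV into CaseRecords."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, comment="#", dtype={"case_id": str})
    if "case_id" not in frame.columns:
        raise SchemaError("cohort file must have a 'case_id' column")
    unknown = [c for c in frame.columns if c != "case_id" and c not in registry]
    if unknown and not ignore_unknown:
        raise SchemaError(f"unknown indicator columns: {unknown}")
    indicator_cols = [c for c in frame.columns if c in registry]
    dup = frame["case_id"][frame["case_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate case ids: {sorted(set(dup))}")

    cases = []
    for _, row in frame.iterrows():
        responses: dict[str, str] = {}
        for col in indicator_cols:
            v = row[col]
            if pd.isna(v) or v == "":
                responses[col] = MISSING
            else:
                try:
                    n = int(float(v))
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"case {row['case_id']!r}, column {col!r}: "
                        f"expected 1/0/empty, got {v!r}"
                    ) from None
                if n not in (0, 1):
                    raise SchemaError(
                        f"case {row['case_id']!r}, column {col!r}: "
                        f"expected 1/0/empty, got {v!r}"
                    )
                responses[col] = YES if n == 1 else NO
        cases.append(CaseRecord(case_id=str(row["case_id"]), responses=responses))
    if not cases:
        raise SchemaError(f"cohort file {path} contains no cases")
    return cases


def write_cohort(cases: Sequence[CaseRecord], registry: IndicatorRegistry,
                 path: str | Path) -> None:
    """Write CaseRecords back to the cohort CSV dialect."""
    rows = []
    for case in cases:
        row: dict[str, object] = {"case_id": case.case_id}
        for ind in registry:
            r = case.responses.get(ind.code, MISSING)
            row[ind.code] = "" if r == MISSING else (1 if r == YES else 0)
        rows.append(row)
    pd.DataFrame(rows, columns=["case_id"] + registry.codes).to_csv(
        path, index=False
    )


def write_posteriors(profiles: Sequence[PosteriorProfile],
                     path: str | Path) -> None:
    """Per-case posterior CSV: case_id, p_samm, n_positive, one column per cause."""
    if not profiles:
        raise InterSAMMError("no profiles to write")
    cause_codes = profiles[0].cause_codes
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "case_id": p.case_id,
            "p_samm": p.p_samm,
            "n_positive": p.n_positive,
        }
        row.update({c: v for c, v in zip(cause_codes, p.p_cause)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trace(profiles: Sequence[PosteriorProfile], path: str | Path) -> None:
    """Row-per-update trace TSV: the prior row then one row per indicator."""
    if not profiles:
        raise InterSAMMError("no profiles to write")
    cause_codes = profiles[0].cause_codes
    rows = []
    for p in profiles:
        for step_no, step in enumerate(p.trace, start=1):
            row: dict[str, object] = {
                "case_id": p.case_id,
                "step": step_no,
                "indicator": step.indicator,
                "p_samm": step.p_samm,
            }
            row.update({c: v for c, v in zip(cause_codes, step.p_cause)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
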