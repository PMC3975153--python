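"""Comparison of probabilistic output against categorical references.

A reference classification — a clinician's case review or a simulation's
ground truth — gives each case a categorical status and zero or more
cause labels with no attached likelihoods.  To compare population cause
distributions, each reference case's unit mass is split *evenly* between
its causes (no hierarchy can be assumed, and any diagnostic uncertainty
the reviewer felt is lost), mirroring the fractional splitting the
probabilistic method applies with its quantified likelihoods.

The module provides: mapping of foreign cause terminologies into the
registry vocabulary, reference CSMFs, per-cause absolute-difference
reports, column-normalized status cross-tabulations (against 3-level or
2-level reference vocabularies), and aggregation of registry causes into
broad aetiological categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import PopulationSummary
from .classification import (
    MORBID_NON_SAMM,
    SAMM,
    STATUSES,
    UNCOMPLICATED,
    CaseClassification,
)
from .model_registry import CauseRegistry, InterSAMMError, SchemaError

__all__ = [
    "MORBID",
    "CauseMapError",
    "JoinError",
    "ReferenceClassification",
    "CauseMap",
    "AggregationScheme",
    "DEFAULT_BROAD_SCHEME",
    "read_references",
    "reference_csmf",
    "CSMFComparison",
    "compare_csmf",
    "status_crosstab",
    "aggregate_causes",
    "recovery_report",
]

MORBID = "morbid"  # 2-level reference vocabularies collapse both morbid levels
_REF_STATUSES = (UNCOMPLICATED, MORBID, MORBID_NON_SAMM, SAMM)
OTHER = "other"


class CauseMapError(InterSAMMError):
    """Reference cause labels could not be resolved to registry codes."""


class JoinError(InterSAMMError):
    """Estimated and reference case ids do not match."""


@dataclass(frozen=True)
class ReferenceClassification:
    """One case's categorical reference (clinician or truth) classification."""

    case_id: str
    status: str
    causes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in _REF_STATUSES:
            raise SchemaError(
                f"case {self.case_id!r}: unknown reference status {self.status!r}"
            )
        if self.status == UNCOMPLICATED and self.causes:
            raise SchemaError(
                f"case {self.case_id!r}: uncomplicated cases cannot carry causes"
            )


@dataclass(frozen=True)
class CauseMap:
    """Total mapping from foreign cause labels to registry codes.

    Labels may resolve to a registry cause code or to the ``other`` sink;
    an encountered label missing from the map is an error, keeping the
    reconciliation of terminologies explicit and auditable.
    """

    mapping: Mapping[str, str]

    @classmethod
    def identity(cls, cause_codes: Iterable[str]) -> "CauseMap":
        return cls({c: c for c in cause_codes})

    @classmethod
    def from_csv(cls, path: str | Path) -> "CauseMap":
        frame = pd.read_csv(path, comment="#", dtype=str)
        required = {"foreign_label", "registry_code"}
        if not required <= set(frame.columns):
            raise SchemaError(
                f"cause map must have columns {sorted(required)}"
            )
        return cls(dict(zip(frame["foreign_label"], frame["registry_code"])))

    def resolve(self, labels: Iterable[str]) -> list[str]:
        unmapped = sorted({l for l in labels if l not in self.mapping})
        if unmapped:
            raise CauseMapError(f"unmapped cause labels: {unmapped}")
        return [self.mapping[l] for l in labels]


def read_references(path: str | Path) -> list[ReferenceClassification]:
    """Reference CSV: case_id, status, semicolon-separated cause labels."""
    frame = pd.read_csv(path, comment="#", dtype=str).fillna("")
    required = {"case_id", "status", "causes"}
    if not required <= set(frame.columns):
        raise SchemaError(f"reference file must have columns {sorted(required)}")
    refs = []
    for r in frame.itertuples():
        causes = tuple(c.strip() for c in str(r.causes).split(";") if c.strip())
        refs.append(ReferenceClassification(str(r.case_id), str(r.status), causes))
    return refs


def reference_csmf(refs: Sequence[ReferenceClassification],
                   cause_map: CauseMap,
                   cause_codes: Sequence[str]) -> PopulationSummary:
    """Population CSMFs from categorical references by even splitting.

    Each case's unit mass is divided equally among its mapped causes;
    uncomplicated cases fill the uncomplicated bucket; morbid cases with
    no recorded cause count as indeterminate.  There is no uncertainty
    bucket — categorical reviews carry none.
    """
    if not refs:
        raise InterSAMMError("no reference classifications given")
    n = len(refs)
    cause_counts = {c: 0.0 for c in cause_codes}
    uncomplicated = 0.0
    indeterminate = 0.0
    other = 0.0
    status_counts = {s: 0 for s in STATUSES}
    for ref in refs:
        if ref.status in status_counts:
            status_counts[ref.status] += 1
        if ref.status == UNCOMPLICATED:
            uncomplicated += 1.0
            continue
        if not ref.causes:
            indeterminate += 1.0
            continue
        mapped = cause_map.resolve(ref.causes)
        share = 1.0 / len(mapped)
        for code in mapped:
            if code == OTHER:
                other += share
            elif code in cause_counts:
                cause_counts[code] += share
            else:
                raise CauseMapError(
                    f"case {ref.case_id!r}: mapped code {code!r} is neither a "
                    f"registry cause nor {OTHER!r}"
                )
    return PopulationSummary(
        n_cases=n,
        status_fractions={s: status_counts[s] / n for s in STATUSES},
        csmf={c: cause_counts[c] / n for c in cause_codes},
        uncomplicated_fraction=uncomplicated / n,
        indeterminate_fraction=indeterminate / n,
        uncertainty_fraction=0.0,
        other_fraction=other / n,
        scope="reference",
    )


@dataclass(frozen=True)
class CSMFComparison:
    """Per-cause absolute differences between two CSMF vectors."""

    differences: Mapping[str, float]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.differences.values())))

    @property
    def min(self) -> float:
        return float(np.min(list(self.differences.values())))

    @property
    def max(self) -> float:
        return float(np.max(list(self.differences.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"abs_difference": pd.Series(dict(self.differences))}
        )


def compare_csmf(est: PopulationSummary, ref: PopulationSummary) -> CSMFComparison:
    """Absolute CSMF differences over the determinate causes only.

    Uncomplicated, uncertainty, indeterminate and other buckets are
    excluded — they are not comparable between a probabilistic and a
    categorical summary.  Symmetric in its arguments.
    """
    if list(est.csmf) != list(ref.csmf):
        raise SchemaError(
            "summaries cover different cause registries: "
            f"{list(est.csmf)} vs {list(ref.csmf)}"
        )
    diffs = {c: abs(est.csmf[c] - ref.csmf[c]) for c in est.csmf}
    if not diffs:
        raise InterSAMMError("no determinate causes to compare")
    return CSMFComparison(diffs)


def status_crosstab(classifications: Sequence[CaseClassification],
                    references: Sequence[ReferenceClassification],
                    ref_levels: int = 3) -> pd.DataFrame:
    """Column-normalized status agreement table.

    Rows are the probabilistic statuses, columns the reference statuses
    (3-level, or 2-level where the reference only distinguishes morbid
    from non-morbid; 3-level references collapse via
    morbid = morbid_non_samm ∪ samm).  Cells are column percentages.
    """
    if ref_levels not in (2, 3):
        raise InterSAMMError("ref_levels must be 2 or 3")
    est_by_id = {c.case_id: c for c in classifications}
    ref_by_id = {r.case_id: r for r in references}
    missing = set(est_by_id) ^ set(ref_by_id)
    if missing:
        raise JoinError(
            f"{len(missing)} case ids present on only one side of the join"
        )
    ref_cols = ([UNCOMPLICATED, MORBID] if ref_levels == 2
                else [UNCOMPLICATED, MORBID_NON_SAMM, SAMM])
    counts = pd.DataFrame(0.0, index=list(STATUSES), columns=ref_cols)
    for case_id, est in est_by_id.items():
        ref_status = ref_by_id[case_id].status
        if ref_levels == 2 and ref_status in (MORBID_NON_SAMM, SAMM):
            ref_status = MORBID
        if ref_levels == 3 and ref_status == MORBID:
            raise SchemaError(
                f"case {case_id!r}: 2-level reference status {MORBID!r} cannot "
                "fill a 3-level table"
            )
        counts.loc[est.status, ref_status] += 1.0
    col_totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = 100.0 * counts / col_totals
    return table.fillna(0.0)


@dataclass(frozen=True)
class AggregationScheme:
    """Mapping from registry causes to broad aetiological categories."""

    mapping: Mapping[str, str]

    def broad_categories(self) -> list[str]:
        seen: list[str] = []
        for broad in self.mapping.values():
            if broad not in seen:
                seen.append(broad)
        return seen


#: Broad categories of similar aetiology over the default cause registry:
#: pre-eclampsia and eclampsia form pregnancy-induced hypertension (PIH);
#: uterine rupture/pre-rupture and obstructed labour form dystocia; the two
#: haemorrhages merge; all infections (incl. malaria) merge; anaemia stands
#: alone.
DEFAULT_BROAD_SCHEME = AggregationScheme({
    "preeclampsia": "PIH",
    "eclampsia": "PIH",
    "uterine_rupture": "Dystocia",
    "obstructed_labour": "Dystocia",
    "antepartum_haemorrhage": "Haemorrhage",
    "postpartum_haemorrhage": "Haemorrhage",
    "puerperal_infection": "Infection",
    "malaria": "Infection",
    "other_infection": "Infection",
    "anaemia": "Anaemia",
})


def aggregate_causes(summary: PopulationSummary,
                     scheme: AggregationScheme) -> PopulationSummary:
    """Sum CSMFs of member causes into broad categories; other buckets pass."""
    missing = [c for c in summary.csmf if c not in scheme.mapping]
    if missing:
        raise SchemaError(f"aggregation scheme does not cover causes: {missing}")
    broad = {b: 0.0 for b in scheme.broad_categories()}
    for code, value in summary.csmf.items():
        broad[scheme.mapping[code]] += value
    return PopulationSummary(
        n_cases=summary.n_cases,
        status_fractions=dict(summary.status_fractions),
        csmf=broad,
        uncomplicated_fraction=summary.uncomplicated_fraction,
        non_scope_fraction=summary.non_scope_fraction,
        indeterminate_fraction=summary.indeterminate_fraction,
        uncertainty_fraction=summary.uncertainty_fraction,
        other_fraction=summary.other_fraction,
        scope=summary.scope,
    )


def recovery_report(summary: PopulationSummary,
                    true_csmf: Mapping[str, float]) -> CSMFComparison:
    """Compare an estimated summary against a known generating CSMF.

    Both vectors are placed on the conditional (sums-to-one) scale over
    the causes named by ``true_csmf`` before differencing, since a
    generating CSMF is defined among morbid cases only.
    """
    est = summary.determinate_csmf(normalize=True)
    missing = [c for c in true_csmf if c not in est.index]
    if missing:
        raise SchemaError(f"summary lacks causes named by the truth: {missing}")
    diffs = {c: abs(float(est[c]) - float(true_csmf[c])) for c in true_csmf}
    return CSMFComparison(diffs)
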