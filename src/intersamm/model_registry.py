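"""Indicator and cause vocabularies and the prior-probability matrix.

The probabilistic morbidity model is parameterised by a single matrix of
prior probabilities:

* ``P(SAMM)`` — the unconditional probability that a pregnancy/delivery
  involves severe acute maternal morbidity (a "near-miss");
* ``P(C)`` — the unconditional probability of each substantive morbidity
  cause category;
* ``P(I)`` — the baseline probability that a woman reports each indicator
  (sign, symptom or care event), morbid or not;
* ``P(I|C)`` — the probability of reporting indicator I given cause C;
* ``P(I|SAMM)`` — the probability of reporting indicator I given any
  severe morbidity (used by the all-cause track of the Bayes engine).

Probabilities are authored on a quantized semi-qualitative scale
(:class:`QuantScale`): experts grade each (indicator, cause) pair rather
than invent raw numbers.  The default registries ship 72 indicators and 10
direct/indirect cause categories; the default matrix packaged with this
distribution is ILLUSTRATIVE — authored for plausibility, not elicited
from experts or fitted to data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InterSAMMError",
    "SchemaError",
    "RangeError",
    "DegeneratePriorError",
    "UnknownGradeError",
    "Indicator",
    "CauseCategory",
    "IndicatorRegistry",
    "CauseRegistry",
    "QuantScale",
    "DEFAULT_SCALE",
    "RESERVED_CAUSE_CODES",
    "PriorMatrix",
    "grade_to_probability",
    "derive_baseline_negative",
    "load_matrix",
    "save_matrix",
    "default_indicator_registry",
    "default_cause_registry",
    "default_matrix",
]

EPS = 1e-6

#: Labels that may appear in classification/aggregation output but are never
#: columns of a prior matrix: they are bookkeeping channels, not hypotheses.
RESERVED_CAUSE_CODES = ("uncomplicated", "indeterminate", "uncertainty", "other")

PRIOR_ROW = "__PRIOR__"
BASELINE_COL = "P_I"
SAMM_COND_COL = "P_I_SAMM"
SAMM_PRIOR_COL = "P_SAMM"


class InterSAMMError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(InterSAMMError):
    """A file or table does not match the expected schema."""


class RangeError(InterSAMMError):
    """A probability value lies outside its legal range."""


class DegeneratePriorError(InterSAMMError):
    """A prior of exactly 0 or 1 makes the Bayesian update undefined."""


class UnknownGradeError(InterSAMMError, KeyError):
    """A grade label is not part of the quantized scale."""


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Indicator:
    """One self-reported sign/symptom/care-event indicator."""

    code: str
    label: str
    index: int  # 1-based position in the canonical registry order


@dataclass(frozen=True)
class CauseCategory:
    """One morbidity cause category (substantive) or bookkeeping label."""

    code: str
    label: str
    kind: str = "substantive"  # or "reserved"

    def __post_init__(self) -> None:
        if self.kind not in ("substantive", "reserved"):
            raise ValueError(f"unknown cause kind {self.kind!r}")


class IndicatorRegistry:
    """Ordered, code-unique collection of indicators."""

    def __init__(self, indicators: Iterable[Indicator]):
        items = list(indicators)
        codes = [ind.code for ind in items]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaError(f"duplicate indicator codes: {dup}")
        if sorted(ind.index for ind in items) != list(range(1, len(items) + 1)):
            raise SchemaError("indicator indices must be a bijection onto 1..n")
        self._items = sorted(items, key=lambda ind: ind.index)
        self._by_code = {ind.code: ind for ind in self._items}

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Indicator]:
        return iter(self._items)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Indicator:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemaError(f"unknown indicator code {code!r}") from None

    @property
    def codes(self) -> list[str]:
        return [ind.code for ind in self._items]

    def position(self, code: str) -> int:
        """0-based array position of an indicator code."""
        return self[code].index - 1


class CauseRegistry:
    """Substantive cause categories plus the reserved bookkeeping labels."""

    def __init__(self, causes: Iterable[CauseCategory]):
        items = list(causes)
        codes = [c.code for c in items]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaError(f"duplicate cause codes: {dup}")
        for c in items:
            if c.kind == "substantive" and c.code in RESERVED_CAUSE_CODES:
                raise SchemaError(
                    f"cause code {c.code!r} is reserved and cannot be substantive"
                )
        self._items = items
        self._by_code = {c.code: c for c in items}

    def __len__(self) -> int:
        return len(self.substantive)

    def __iter__(self) -> Iterator[CauseCategory]:
        return iter(self._items)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> CauseCategory:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemaError(f"unknown cause code {code!r}") from None

    @property
    def substantive(self) -> list[CauseCategory]:
        return [c for c in self._items if c.kind == "substantive"]

    @property
    def codes(self) -> list[str]:
        """Codes of the substantive causes, in registry order."""
        return [c.code for c in self.substantive]

    def position(self, code: str) -> int:
        """0-based position of a substantive cause code."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise SchemaError(f"unknown substantive cause code {code!r}") from None


# ---------------------------------------------------------------------------
# Quantized semi-qualitative scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantScale:
    """Ordered (grade label, probability) pairs, strictly decreasing in (0,1].

    Experts grade how strongly an indicator is expected under a cause; the
    grade maps to a fixed probability.  The default scale spans near-certain
    (``I``) down to very unlikely (``E``).
    """

    grades: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.grades) < 5:
            raise ValueError("a quantized scale needs at least 5 grades")
        values = [v for _, v in self.grades]
        labels = [g for g, _ in self.grades]
        if len(set(labels)) != len(labels):
            raise ValueError("grade labels must be unique")
        if any(not (0.0 < v <= 1.0) for v in values):
            raise ValueError("grade values must lie in (0, 1]")
        if any(b >= a for a, b in zip(values, values[1:])):
            raise ValueError("grade values must be strictly decreasing")

    @property
    def labels(self) -> list[str]:
        return [g for g, _ in self.grades]

    def __getitem__(self, grade: str) -> float:
        for g, v in self.grades:
            if g == grade:
                return v
        raise UnknownGradeError(grade)

    def floor(self, p: float) -> float:
        """Largest grade value ≤ p (smallest grade if p is below all)."""
        candidates = [v for _, v in self.grades if v <= p]
        return max(candidates) if candidates else self.grades[-1][1]


DEFAULT_SCALE = QuantScale((
    ("I", 1.0 - EPS),   # near-certain
    ("A", 0.5),         # very likely / common
    ("B", 0.1),         # likely
    ("C", 0.02),        # possible
    ("D", 0.005),       # unlikely
    ("E", 0.001),       # very unlikely
))


def grade_to_probability(grade: str, scale: QuantScale = DEFAULT_SCALE) -> float:
    """Map a grade label to its probability on the quantized scale."""
    return scale[grade]


# ---------------------------------------------------------------------------
# Prior matrix
# ---------------------------------------------------------------------------

@dataclass
class PriorMatrix:
    """All prior probabilities parameterising the morbidity model.

    Arrays are aligned to registry order: ``conditional[i, c]`` is
    P(indicator i | cause c) with ``i`` the 0-based indicator position and
    ``c`` the 0-based substantive-cause position.
    """

    indicators: IndicatorRegistry
    causes: CauseRegistry
    prior_samm: float
    prior_cause: np.ndarray          # (n_causes,)  P(C)
    baseline_indicator: np.ndarray   # (n_ind,)     P(I)
    conditional: np.ndarray          # (n_ind, n_causes)  P(I|C)
    conditional_samm: np.ndarray     # (n_ind,)     P(I|SAMM)

    def __post_init__(self) -> None:
        self.prior_cause = np.asarray(self.prior_cause, dtype=float)
        self.baseline_indicator = np.asarray(self.baseline_indicator, dtype=float)
        self.conditional = np.asarray(self.conditional, dtype=float)
        self.conditional_samm = np.asarray(self.conditional_samm, dtype=float)
        self.validate()

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_causes(self) -> int:
        return len(self.causes)

    def validate(self) -> None:
        ni, nc = self.n_indicators, self.n_causes
        if self.prior_cause.shape != (nc,):
            raise SchemaError(f"prior_cause must have shape ({nc},)")
        if self.baseline_indicator.shape != (ni,):
            raise SchemaError(f"baseline_indicator must have shape ({ni},)")
        if self.conditional.shape != (ni, nc):
            raise SchemaError(f"conditional must have shape ({ni}, {nc})")
        if self.conditional_samm.shape != (ni,):
            raise SchemaError(f"conditional_samm must have shape ({ni},)")
        self._check_open_unit("P(SAMM)", np.asarray([self.prior_samm]))
        self._check_open_unit("P(C)", self.prior_cause, self.causes.codes)
        self._check_open_unit("P(I)", self.baseline_indicator, self.indicators.codes)
        self._check_open_unit("P(I|SAMM)", self.conditional_samm, self.indicators.codes)
        bad = np.argwhere((self.conditional <= 0.0) | (self.conditional >= 1.0))
        if bad.size:
            i, c = bad[0]
            raise RangeError(
                f"P(I|C) out of (0,1) at indicator "
                f"{self.indicators.codes[i]!r}, cause {self.causes.codes[c]!r}: "
                f"{self.conditional[i, c]}"
            )
        if self.prior_cause.sum() > 1.0 + 1e-12:
            raise RangeError(
                f"sum of cause priors is {self.prior_cause.sum():.6f} > 1; the "
                "residual mass must cover uncomplicated/unspecified deliveries"
            )

    @staticmethod
    def _check_open_unit(name: str, values: np.ndarray,
                         labels: Sequence[str] | None = None) -> None:
        bad = np.flatnonzero((values <= 0.0) | (values >= 1.0))
        if bad.size:
            where = labels[bad[0]] if labels is not None else ""
            raise RangeError(
                f"{name} out of (0,1)" + (f" at {where!r}" if where else "")
                + f": {values[bad[0]]}"
            )

    def normalized_cause_prior(self) -> np.ndarray:
        """P(C) renormalized to a proper distribution over the causes."""
        return self.prior_cause / self.prior_cause.sum()

    def copy(self) -> "PriorMatrix":
        return replace(
            self,
            prior_cause=self.prior_cause.copy(),
            baseline_indicator=self.baseline_indicator.copy(),
            conditional=self.conditional.copy(),
            conditional_samm=self.conditional_samm.copy(),
        )


def derive_baseline_negative(matrix: PriorMatrix, indicator: str | int) -> float:
    """P(I | no severe morbidity), decomposed from P(I), P(I|SAMM), P(SAMM).

    By total probability, P(I) = P(I|S)·P(S) + P(I|¬S)·(1−P(S)), hence

        P(I|¬S) = (P(I) − P(I|S)·P(S)) / (1 − P(S)).

    The result is clamped to [eps, 1−eps]; a clamp means the stated P(I) is
    incoherent with P(I|SAMM)·P(SAMM) and a warning is emitted.
    """
    if isinstance(indicator, str):
        i = matrix.indicators.position(indicator)
    else:
        i = int(indicator)
    p_s = matrix.prior_samm
    if p_s >= 1.0:
        raise DegeneratePriorError("P(SAMM) = 1 leaves no uncomplicated stratum")
    p_i = matrix.baseline_indicator[i]
    p_i_s = matrix.conditional_samm[i]
    value = (p_i - p_i_s * p_s) / (1.0 - p_s)
    if not (EPS <= value <= 1.0 - EPS):
        warnings.warn(
            f"P(I|not SAMM) for indicator {matrix.indicators.codes[i]!r} "
            f"({value:.3g}) clamped into [{EPS}, {1 - EPS}]; the baseline P(I) "
            "is incoherent with P(I|SAMM) and P(SAMM)",
            stacklevel=2,
        )
        value = min(max(value, EPS), 1.0 - EPS)
    return float(value)


def baseline_negative_vector(matrix: PriorMatrix) -> np.ndarray:
    """Vector of P(I|¬SAMM) over all indicators (clamped, no warnings)."""
    p_s = matrix.prior_samm
    if p_s >= 1.0:
        raise DegeneratePriorError("P(SAMM) = 1 leaves no uncomplicated stratum")
    v = (matrix.baseline_indicator - matrix.conditional_samm * p_s) / (1.0 - p_s)
    return np.clip(v, EPS, 1.0 - EPS)


# ---------------------------------------------------------------------------
# Matrix file I/O
#
# One self-contained, diff-able CSV: first column = indicator code, one
# column per cause code, plus P_I (baseline), P_I_SAMM (conditional on any
# severe morbidity) and P_SAMM.  A special __PRIOR__ row carries P(C) per
# cause and P(SAMM); indicator rows leave P_SAMM empty.  Lines starting
# with '#' are comments.
# ---------------------------------------------------------------------------

def save_matrix(matrix: PriorMatrix, path: str | Path,
                header_comment: str | None = None) -> None:
    """Write a PriorMatrix to its CSV representation."""
    path = Path(path)
    cause_codes = matrix.causes.codes
    cols = ["indicator", BASELINE_COL, SAMM_COND_COL, SAMM_PRIOR_COL] + cause_codes
    rows: list[dict[str, object]] = []
    prior_row: dict[str, object] = {
        "indicator": PRIOR_ROW,
        BASELINE_COL: "",
        SAMM_COND_COL: "",
        SAMM_PRIOR_COL: repr(matrix.prior_samm),
    }
    for c, code in enumerate(cause_codes):
        prior_row[code] = repr(float(matrix.prior_cause[c]))
    rows.append(prior_row)
    for i, code in enumerate(matrix.indicators.codes):
        row: dict[str, object] = {
            "indicator": code,
            BASELINE_COL: repr(float(matrix.baseline_indicator[i])),
            SAMM_COND_COL: repr(float(matrix.conditional_samm[i])),
            SAMM_PRIOR_COL: "",
        }
        for c, ccode in enumerate(cause_codes):
            row[ccode] = repr(float(matrix.conditional[i, c]))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cols)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def load_matrix(path: str | Path,
                indicator_registry: IndicatorRegistry | None = None,
                cause_registry: CauseRegistry | None = None) -> PriorMatrix:
    """Read and validate a prior-matrix CSV.

    When registries are given, the file must cover every registry indicator
    and cause exactly once (extra or missing entries are schema errors);
    otherwise registries are constructed from the file itself.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"matrix file not found: {path}")
    frame = pd.read_csv(path, comment="#", dtype={"indicator": str})
    required = {"indicator", BASELINE_COL, SAMM_COND_COL, SAMM_PRIOR_COL}
    missing_cols = required - set(frame.columns)
    if missing_cols:
        raise SchemaError(f"matrix file missing columns: {sorted(missing_cols)}")
    cause_cols = [c for c in frame.columns if c not in required]
    reserved = sorted(set(cause_cols) & set(RESERVED_CAUSE_CODES))
    if reserved:
        raise SchemaError(f"reserved cause codes may not be matrix columns: {reserved}")

    prior_rows = frame[frame["indicator"] == PRIOR_ROW]
    if len(prior_rows) != 1:
        raise SchemaError(f"matrix file must contain exactly one {PRIOR_ROW} row")
    body = frame[frame["indicator"] != PRIOR_ROW].reset_index(drop=True)
    dup = body["indicator"][body["indicator"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate indicator rows: {sorted(set(dup))}")

    file_indicators = body["indicator"].tolist()
    if indicator_registry is None:
        indicator_registry = IndicatorRegistry(
            Indicator(code, code, i + 1) for i, code in enumerate(file_indicators)
        )
    else:
        missing = [c for c in indicator_registry.codes if c not in file_indicators]
        extra = [c for c in file_indicators if c not in indicator_registry]
        if missing:
            raise SchemaError(f"matrix file lacks registry indicators: {missing}")
        if extra:
            raise SchemaError(f"matrix file has unknown indicators: {extra}")
    if cause_registry is None:
        cause_registry = CauseRegistry(
            [CauseCategory(code, code) for code in cause_cols]
            + [CauseCategory(code, code, kind="reserved")
               for code in RESERVED_CAUSE_CODES]
        )
    else:
        missing = [c for c in cause_registry.codes if c not in cause_cols]
        extra = [c for c in cause_cols if c not in cause_registry.codes]
        if missing:
            raise SchemaError(f"matrix file lacks registry causes: {missing}")
        if extra:
            raise SchemaError(f"matrix file has unknown causes: {extra}")

    cause_codes = cause_registry.codes
    body = body.set_index("indicator").loc[indicator_registry.codes]

    def cell(frame_row: str, col: str, value: object) -> float:
        try:
            v = float(value)
        except (TypeError, ValueError):
            raise SchemaError(
                f"non-numeric value at row {frame_row!r}, column {col!r}: {value!r}"
            ) from None
        if not (0.0 < v < 1.0):
            raise RangeError(
                f"value out of (0,1) at row {frame_row!r}, column {col!r}: {v}"
            )
        return v

    prior = prior_rows.iloc[0]
    prior_samm = cell(PRIOR_ROW, SAMM_PRIOR_COL, prior[SAMM_PRIOR_COL])
    prior_cause = np.array([cell(PRIOR_ROW, c, prior[c]) for c in cause_codes])
    baseline = np.array(
        [cell(code, BASELINE_COL, body.loc[code, BASELINE_COL])
         for code in indicator_registry.codes]
    )
    cond_samm = np.array(
        [cell(code, SAMM_COND_COL, body.loc[code, SAMM_COND_COL])
         for code in indicator_registry.codes]
    )
    conditional = np.array(
        [[cell(code, c, body.loc[code, c]) for c in cause_codes]
         for code in indicator_registry.codes]
    )
    return PriorMatrix(
        indicators=indicator_registry,
        causes=cause_registry,
        prior_samm=prior_samm,
        prior_cause=prior_cause,
        baseline_indicator=baseline,
        conditional=conditional,
        conditional_samm=cond_samm,
    )


# ---------------------------------------------------------------------------
# Packaged defaults
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("intersamm").joinpath("data", name)))


def default_indicator_registry() -> IndicatorRegistry:
    """The 72 canonical sign/symptom indicators."""
    frame = pd.read_csv(_data_path("indicators.csv"), comment="#")
    return IndicatorRegistry(
        Indicator(str(r.code), str(r.label), int(r.index))
        for r in frame.itertuples()
    )


def default_cause_registry() -> CauseRegistry:
    """The 10 direct/indirect cause categories plus reserved labels."""
    frame = pd.read_csv(_data_path("causes.csv"), comment="#")
    causes = [
        CauseCategory(str(r.code), str(r.label), kind="substantive")
        for r in frame.itertuples()
    ]
    causes += [
        CauseCategory(code, code.replace("_", " ").title(), kind="reserved")
        for code in RESERVED_CAUSE_CODES
    ]
    return CauseRegistry(causes)


def default_matrix() -> PriorMatrix:
    """The packaged ILLUSTRATIVE prior matrix over the default registries."""
    return load_matrix(
        _data_path("default_matrix.csv"),
        default_indicator_registry(),
        default_cause_registry(),
    )
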