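"""Domain types and readers/writers for diagnostic accuracy study data.

A diagnostic accuracy study records, per subject, the true disease condition
(or a reference-standard result standing in for it), the index test result,
and any *interfering events* (IEs) — incidents after study inclusion that
affect the test result or leave no test decision at all.

Two result states are deliberately distinct and never conflated:

* ``inconclusive`` — a result exists but classifies the subject as neither
  positive nor negative (an intermediate value, or an uninterpretable one
  such as a poor-quality image);
* ``absent`` — no test decision ever came into being (early termination),
  or a collected result was lost. A lost-after-collection value is encoded
  as ``absent`` *with no event occurrence* and is handled by the engine's
  missing-data options, never by an IE strategy.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import ParseError, SchemaError, SpecValidationError

__all__ = [
    "Result",
    "Condition",
    "Decision",
    "StrategyName",
    "EventOccurrence",
    "SubjectRecord",
    "StratumCell",
    "StratifiedCounts",
    "StrategyOptions",
    "EventStrategy",
    "MultiEventPolicy",
    "EstimandSpec",
    "DerivedDecision",
    "read_subject_table",
    "write_subject_table",
    "records_from_frame",
    "records_to_frame",
    "tabulate",
    "read_estimand_spec",
    "write_estimand_spec",
    "spec_to_yaml",
]


class Result(str, Enum):
    """Vocabulary for index, reference, partial, and counterfactual results."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"
    ABSENT = "absent"


class Condition(str, Enum):
    """True disease state with respect to the target condition."""

    DISEASED = "diseased"
    NON_DISEASED = "non_diseased"
    UNKNOWN = "unknown"


class Decision(str, Enum):
    """Post-strategy per-subject test decision."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"
    EXCLUDED = "excluded"
    NEEDS_IMPUTATION = "needs_imputation"


class StrategyName(str, Enum):
    """The six interfering-event handling strategies."""

    DIAGNOSTIC_POLICY = "diagnostic_policy"
    INDICATIVE_EVENT = "indicative_event"
    SETBACK = "setback"
    HYPOTHETICAL = "hypothetical"
    WHILE_UNDER_MONITORING = "while_under_monitoring"
    PRINCIPAL_STRATUM = "principal_stratum"


# ---------------------------------------------------------------------------
# subject-level records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventOccurrence:
    """One interfering-event occurrence (or recorded non-occurrence).

    ``time`` is an ordering key in arbitrary units, used only when several
    events occurred and a first-event policy must pick the governing one.
    """

    event_type: str
    occurred: bool = True
    time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time is not None and self.time < 0:
            raise ParseError(f"event time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant.

    ``partial_result`` is the decision derivable from measurements collected
    before the IE only (the while-under-monitoring strategy's input).
    ``counterfactual_result`` is the result had no IE occurred; it exists
    only for simulated data and serves as the oracle for the hypothetical
    strategy — records read from real-data files always leave it absent.
    """

    subject_id: str
    true_condition: Condition = Condition.UNKNOWN
    reference_result: Result = Result.ABSENT
    index_result: Result = Result.ABSENT
    events: tuple[EventOccurrence, ...] = ()
    partial_result: Result = Result.ABSENT
    counterfactual_result: Result = Result.ABSENT
    inconclusive_subtype: Optional[str] = None  # "intermediate" | "uninterpretable"
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        for fname in ("partial_result", "counterfactual_result"):
            val = getattr(self, fname)
            if val is Result.INCONCLUSIVE:
                raise ParseError(
                    f"{fname} must be positive, negative or absent; got inconclusive"
                )
        if not self.occurred_events and self.partial_result is not Result.ABSENT:
            if self.partial_result != self.index_result:
                raise ParseError(
                    f"subject {self.subject_id}: with no occurred event the partial "
                    "result must equal the index result or be absent"
                )

    @property
    def occurred_events(self) -> tuple[EventOccurrence, ...]:
        return tuple(e for e in self.events if e.occurred)

    def has_event(self, event_type: str) -> bool:
        return any(e.occurred and e.event_type == event_type for e in self.events)

    def with_condition(self, condition: Condition) -> "SubjectRecord":
        return replace(self, true_condition=condition)


@dataclass
class DerivedDecision:
    """The post-strategy decision for one subject, with provenance."""

    subject_id: str
    decision: Decision
    source: str
    stratum_membership: Optional[str] = None


# ---------------------------------------------------------------------------
# stratified counts (disease state x IE occurrence x test result)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumCell:
    """Result counts within one (disease state, IE stratum) cell."""

    positive: int = 0
    negative: int = 0
    inconclusive: int = 0
    absent: int = 0

    def __post_init__(self) -> None:
        for name in ("positive", "negative", "inconclusive", "absent"):
            if getattr(self, name) < 0:
                raise ParseError(f"cell count {name} must be non-negative")

    @property
    def conclusive(self) -> int:
        return self.positive + self.negative

    @property
    def total(self) -> int:
        return self.positive + self.negative + self.inconclusive + self.absent


@dataclass(frozen=True)
class StratifiedCounts:
    """Counts cross-classified by disease state and IE occurrence.

    The conclusive 2x2x2 core carries positive/negative counts; inconclusive
    and absent results are kept in overflow fields of each cell so that the
    table always accounts for every subject.
    """

    diseased_without_ie: StratumCell = StratumCell()
    diseased_with_ie: StratumCell = StratumCell()
    healthy_without_ie: StratumCell = StratumCell()
    healthy_with_ie: StratumCell = StratumCell()
    event_type: Optional[str] = None

    @property
    def n_diseased(self) -> int:
        return self.diseased_without_ie.total + self.diseased_with_ie.total

    @property
    def n_healthy(self) -> int:
        return self.healthy_without_ie.total + self.healthy_with_ie.total

    @property
    def n_total(self) -> int:
        return self.n_diseased + self.n_healthy

    def to_records(self, event_type: Optional[str] = None) -> list[SubjectRecord]:
        """Synthesize minimal subject records reproducing every cell count."""
        event_type = event_type or self.event_type or "ie"
        records: list[SubjectRecord] = []
        i = 0
        cells = [
            (Condition.DISEASED, False, self.diseased_without_ie),
            (Condition.DISEASED, True, self.diseased_with_ie),
            (Condition.NON_DISEASED, False, self.healthy_without_ie),
            (Condition.NON_DISEASED, True, self.healthy_with_ie),
        ]
        for condition, with_ie, cell in cells:
            for result, count in (
                (Result.POSITIVE, cell.positive),
                (Result.NEGATIVE, cell.negative),
                (Result.INCONCLUSIVE, cell.inconclusive),
                (Result.ABSENT, cell.absent),
            ):
                for _ in range(count):
                    i += 1
                    events = (EventOccurrence(event_type),) if with_ie else ()
                    records.append(
                        SubjectRecord(
                            subject_id=f"s{i:04d}",
                            true_condition=condition,
                            reference_result=(
                                Result.POSITIVE
                                if condition is Condition.DISEASED
                                else Result.NEGATIVE
                            ),
                            index_result=result,
                            events=events,
                        )
                    )
        return records


def tabulate(records: Iterable[SubjectRecord], event_type: str) -> StratifiedCounts:
    """Cross-classify records by disease state, IE occurrence, and result.

    Every record must carry a known ``true_condition``; resolve the reference
    standard first (see the engine's ``resolve_condition``) when working at
    study level.
    """
    tally: dict[tuple[Condition, bool], dict[Result, int]] = {
        (c, b): {r: 0 for r in Result}
        for c in (Condition.DISEASED, Condition.NON_DISEASED)
        for b in (False, True)
    }
    for rec in records:
        if rec.true_condition is Condition.UNKNOWN:
            raise ParseError(
                f"subject {rec.subject_id}: true condition unknown; apply "
                "reference-standard handling (resolve_condition) before tabulating"
            )
        tally[(rec.true_condition, rec.has_event(event_type))][rec.index_result] += 1

    def cell(condition: Condition, with_ie: bool) -> StratumCell:
        t = tally[(condition, with_ie)]
        return StratumCell(
            positive=t[Result.POSITIVE],
            negative=t[Result.NEGATIVE],
            inconclusive=t[Result.INCONCLUSIVE],
            absent=t[Result.ABSENT],
        )

    return StratifiedCounts(
        diseased_without_ie=cell(Condition.DISEASED, False),
        diseased_with_ie=cell(Condition.DISEASED, True),
        healthy_without_ie=cell(Condition.NON_DISEASED, False),
        healthy_with_ie=cell(Condition.NON_DISEASED, True),
        event_type=event_type,
    )


# ---------------------------------------------------------------------------
# estimand specification (five attributes, declarative and serializable)
# ---------------------------------------------------------------------------

MeasureName = Literal[
    "sensitivity", "specificity", "youden", "lr_positive", "lr_negative", "ppv", "npv"
]

#: option keys each strategy requires / accepts
_REQUIRED_OPTIONS: dict[StrategyName, set[str]] = {
    StrategyName.INDICATIVE_EVENT: {"fixed_result"},
    StrategyName.PRINCIPAL_STRATUM: {"stratum"},
    StrategyName.HYPOTHETICAL: {"imputer"},
}
_ALLOWED_OPTIONS: dict[StrategyName, set[str]] = {
    StrategyName.DIAGNOSTIC_POLICY: {"imputer"},
    StrategyName.INDICATIVE_EVENT: {"fixed_result"},
    StrategyName.SETBACK: {"imputer"},
    StrategyName.HYPOTHETICAL: {"imputer"},
    StrategyName.WHILE_UNDER_MONITORING: {"partial_rule"},
    StrategyName.PRINCIPAL_STRATUM: {"stratum"},
}


class StrategyOptions(BaseModel):
    """Options attached to one strategy assignment.

    Each field is meaningful only for the strategies that declare it:
    ``fixed_result`` for the indicative-event strategy, ``stratum`` for the
    principal-stratum strategy, ``imputer`` for hypothetical (required) and
    for diagnostic-policy / setback (when results or the condition can be
    absent), ``partial_rule`` for while-under-monitoring.
    """

    model_config = ConfigDict(extra="forbid")

    fixed_result: Optional[Literal["positive", "negative"]] = None
    stratum: Optional[Literal["event_free", "event_affected"]] = None
    imputer: Optional[str] = None
    partial_rule: Optional[str] = None

    def set_keys(self) -> set[str]:
        return {k for k, v in self.model_dump().items() if v is not None}


class EventStrategy(BaseModel):
    """A strategy assignment for one declared interfering-event type."""

    model_config = ConfigDict(extra="forbid")

    strategy: StrategyName
    options: StrategyOptions = StrategyOptions()

    @model_validator(mode="after")
    def _check_options(self) -> "EventStrategy":
        given = self.options.set_keys()
        allowed = _ALLOWED_OPTIONS[self.strategy]
        required = _REQUIRED_OPTIONS.get(self.strategy, set())
        extra = given - allowed
        if extra:
            raise ValueError(
                f"option(s) {sorted(extra)} are not valid for strategy "
                f"'{self.strategy.value}' (allowed: {sorted(allowed) or 'none'})"
            )
        missing = required - given
        if missing:
            raise ValueError(
                f"strategy '{self.strategy.value}' requires option(s) {sorted(missing)}"
            )
        return self


class MultiEventPolicy(BaseModel):
    """How to reduce several occurred events to a single governing one."""

    model_config = ConfigDict(extra="forbid")

    policy: Literal["first_event", "priority"] = "first_event"
    priority: list[str] = []

    @model_validator(mode="after")
    def _check(self) -> "MultiEventPolicy":
        if self.policy == "priority" and not self.priority:
            raise ValueError("priority policy requires a non-empty priority order")
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority order must not repeat event types")
        return self


class PopulationSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    description: str = ""
    #: pandas-query expression over covariate columns; None keeps everyone
    filter_query: Optional[str] = None


class TargetConditionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    definition: str = ""


class IndexTestSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rule: str
    description: str = ""


class EstimandSpec(BaseModel):
    """The five attributes of a diagnostic accuracy estimand.

    Population, target condition, index test (with its decision rule),
    accuracy measure(s), and a strategy for every declared interfering
    event. A change to any attribute defines a different estimand, i.e. a
    different clinical question.
    """

    model_config = ConfigDict(extra="forbid")

    spec_version: int = 1
    population: PopulationSpec = PopulationSpec()
    target_condition: TargetConditionSpec
    index_test: IndexTestSpec
    accuracy_measures: list[MeasureName]
    strategy_map: dict[str, EventStrategy] = {}
    multi_event_policy: MultiEventPolicy = MultiEventPolicy()
    #: "true_condition" reads the estimand-level condition column directly;
    #: "reference" classifies via the reference-standard result (study level)
    condition_source: Literal["true_condition", "reference"] = "true_condition"

    @field_validator("accuracy_measures")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one accuracy measure must be requested")
        return v

    @model_validator(mode="after")
    def _check_priority_covers_events(self) -> "EstimandSpec":
        if self.multi_event_policy.policy == "priority":
            missing = set(self.strategy_map) - set(self.multi_event_policy.priority)
            if missing:
                raise ValueError(
                    f"priority order omits declared event type(s): {sorted(missing)}"
                )
        return self

    def strategy_for(self, event_type: str) -> EventStrategy:
        try:
            return self.strategy_map[event_type]
        except KeyError:
            raise SpecValidationError(
                f"event type '{event_type}' is not declared in the estimand; "
                "every interfering event needs exactly one strategy"
            ) from None


def read_estimand_spec(path: Union[str, Path]) -> EstimandSpec:
    """Read an estimand specification from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        payload = yaml.safe_load(text)  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise SpecValidationError(f"cannot parse estimand spec {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise SpecValidationError(f"estimand spec {path} must be a mapping")
    try:
        return EstimandSpec.model_validate(payload)
    except Exception as exc:  # pydantic.ValidationError
        raise SpecValidationError(f"invalid estimand spec {path}: {exc}") from exc


def spec_to_yaml(spec: EstimandSpec) -> str:
    """Canonical YAML serialization (sorted keys; round-trips bit-identically)."""
    return yaml.safe_dump(
        spec.model_dump(mode="json"), sort_keys=True, default_flow_style=False
    )


def write_estimand_spec(spec: EstimandSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(spec.model_dump(mode="json"), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    else:
        path.write_text(spec_to_yaml(spec), encoding="utf-8")


# ---------------------------------------------------------------------------
# delimited-text subject tables
# ---------------------------------------------------------------------------

_CORE_COLUMNS = (
    "subject_id",
    "true_condition",
    "reference_result",
    "index_result",
    "partial_result",
    "counterfactual_result",
    "inconclusive_subtype",
)

_CONDITION_TOKENS = {
    "diseased": Condition.DISEASED,
    "non_diseased": Condition.NON_DISEASED,
    "non-diseased": Condition.NON_DISEASED,
    "unknown": Condition.UNKNOWN,
    "": Condition.UNKNOWN,
}

_RESULT_TOKENS = {
    "positive": Result.POSITIVE,
    "negative": Result.NEGATIVE,
    "inconclusive": Result.INCONCLUSIVE,
    "absent": Result.ABSENT,
    "": Result.ABSENT,  # an empty cell encodes the absent state, never negative
}


def _parse_result(token: str, column: str, row: int) -> Result:
    try:
        return _RESULT_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(
            f"row {row}: '{token}' is not a valid {column} "
            f"(allowed: positive, negative, inconclusive, absent, empty)"
        ) from None


def _parse_condition(token: str, row: int) -> Condition:
    try:
        return _CONDITION_TOKENS[token.strip().lower()]
    except KeyError:
        raise ParseError(
            f"row {row}: '{token}' is not a valid true_condition "
            f"(allowed: diseased, non_diseased, unknown, empty)"
        ) from None


def _coerce_covariate(token: str) -> object:
    token = token.strip()
    if token == "":
        return None
    try:
        f = float(token)
    except ValueError:
        return token
    return int(f) if f.is_integer() and "." not in token and "e" not in token.lower() else f


def records_from_frame(
    frame: pd.DataFrame, schema: Optional[Mapping[str, str]] = None
) -> list[SubjectRecord]:
    """Convert a string DataFrame (one row per subject) to validated records.

    ``schema`` maps logical core names (``subject_id``, ``index_result``, ...)
    to actual column names. Interfering events live in columns ``ie_<type>``
    (flags: 1/0/true/false/empty) with optional ``ie_<type>_time`` columns;
    anything else becomes a covariate.
    """
    schema = dict(schema or {})
    colmap = {logical: schema.get(logical, logical) for logical in _CORE_COLUMNS}

    if colmap["subject_id"] not in frame.columns:
        raise SchemaError(f"missing required column '{colmap['subject_id']}'")
    if colmap["index_result"] not in frame.columns:
        raise SchemaError(f"missing required column '{colmap['index_result']}'")
    if (
        colmap["true_condition"] not in frame.columns
        and colmap["reference_result"] not in frame.columns
    ):
        raise SchemaError(
            f"missing required column '{colmap['true_condition']}' "
            f"(or '{colmap['reference_result']}')"
        )

    core_present = {
        logical: col for logical, col in colmap.items() if col in frame.columns
    }
    event_cols: dict[str, str] = {}
    time_cols: dict[str, str] = {}
    for col in frame.columns:
        if col.startswith("ie_") and col.endswith("_time"):
            time_cols[col[3:-5]] = col
        elif col.startswith("ie_"):
            event_cols[col[3:]] = col
    consumed = set(core_present.values()) | set(event_cols.values()) | set(
        time_cols.values()
    )
    covariate_cols = [c for c in frame.columns if c not in consumed]

    records: list[SubjectRecord] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        def get(logical: str) -> str:
            col = core_present.get(logical)
            return "" if col is None else str(row[col])

        events: list[EventOccurrence] = []
        for etype, col in sorted(event_cols.items()):
            flag = str(row[col]).strip().lower()
            if flag in ("", "0", "false", "no"):
                continue
            if flag not in ("1", "true", "yes"):
                raise ParseError(
                    f"row {i}: '{row[col]}' is not a valid event flag for ie_{etype}"
                )
            tcol = time_cols.get(etype)
            tval = None if tcol is None else str(row[tcol]).strip()
            time = float(tval) if tval else None
            events.append(EventOccurrence(event_type=etype, occurred=True, time=time))

        covariates = {c: _coerce_covariate(str(row[c])) for c in covariate_cols}
        subtype = get("inconclusive_subtype").strip() or None
        records.append(
            SubjectRecord(
                subject_id=get("subject_id"),
                true_condition=_parse_condition(get("true_condition"), i),
                reference_result=_parse_result(
                    get("reference_result"), "reference_result", i
                ),
                index_result=_parse_result(get("index_result"), "index_result", i),
                events=tuple(events),
                partial_result=_parse_result(
                    get("partial_result"), "partial_result", i
                ),
                counterfactual_result=_parse_result(
                    get("counterfactual_result"), "counterfactual_result", i
                ),
                inconclusive_subtype=subtype,
                covariates=covariates,
            )
        )
    return records


def read_subject_table(
    path: Union[str, Path, io.TextIOBase],
    schema: Optional[Mapping[str, str]] = None,
) -> list[SubjectRecord]:
    """Read subject-level records from a CSV file (UTF-8, header required)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(frame, schema)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Inverse of :func:`records_from_frame`; absent states become empty cells."""
    event_types = sorted({e.event_type for r in records for e in r.events})
    any_time = {
        t: any(
            e.time is not None
            for r in records
            for e in r.events
            if e.event_type == t
        )
        for t in event_types
    }
    covariate_names = sorted({k for r in records for k in r.covariates})

    rows = []
    for r in records:
        row: dict[str, str] = {
            "subject_id": r.subject_id,
            "true_condition": (
                "" if r.true_condition is Condition.UNKNOWN else r.true_condition.value
            ),
            "reference_result": (
                "" if r.reference_result is Result.ABSENT else r.reference_result.value
            ),
            "index_result": (
                "" if r.index_result is Result.ABSENT else r.index_result.value
            ),
            "partial_result": (
                "" if r.partial_result is Result.ABSENT else r.partial_result.value
            ),
            "counterfactual_result": (
                ""
                if r.counterfactual_result is Result.ABSENT
                else r.counterfactual_result.value
            ),
            "inconclusive_subtype": r.inconclusive_subtype or "",
        }
        by_type = {e.event_type: e for e in r.events if e.occurred}
        for t in event_types:
            ev = by_type.get(t)
            row[f"ie_{t}"] = "1" if ev is not None else "0"
            if any_time[t]:
                row[f"ie_{t}_time"] = (
                    "" if ev is None or ev.time is None else repr(ev.time)
                )
        for c in covariate_names:
            v = r.covariates.get(c)
            row[c] = "" if v is None else str(v)
        rows.append(row)

    columns = list(_CORE_COLUMNS)
    for t in event_types:
        columns.append(f"ie_{t}")
        if any_time[t]:
            columns.append(f"ie_{t}_time")
    columns += covariate_names
    return pd.DataFrame(rows, columns=columns)


def write_subject_table(
    records: Sequence[SubjectRecord], path: Union[str, Path]
) -> None:
    """Write records as CSV; round-trips through :func:`read_subject_table`."""
    records_to_frame(records).to_csv(path, index=False)
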