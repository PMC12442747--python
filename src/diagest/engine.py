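"""Estimand engine: from records + estimand specification to an accuracy report.

Pipeline: population filter -> condition resolution (reference standard, if
the estimand is evaluated at study level) -> per-subject event resolution ->
per-event strategy application -> missing/inconclusive handling -> accuracy
measures. Every exclusion and alteration is written to an audit log so the
estimate is traceable to the estimand attribute that produced it.

The engine is exposed as :class:`DiagnosticAccuracyEstimator`, a
scikit-learn style estimator (``fit`` on a list of records or a DataFrame,
fitted attributes with trailing underscores, ``get_params``/``set_params``
for pipeline and grid use); :func:`apply_estimand` is a thin functional
wrapper over it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ImputationError, SpecValidationError, UndefinedEstimateError
from .imputers import get_imputer
from .measures import (
    EXCLUSION_BIAS_WARNING,
    AccuracyReport,
    InconclusivePolicy,
    derived_measures,
    format_sweep_table,
    proportion_with_ci,
    sensitivity,
    specificity,
)
from .strategies import apply_strategy, resolve_events
from .study_data import (
    Condition,
    Decision,
    DerivedDecision,
    EstimandSpec,
    EventStrategy,
    IndexTestSpec,
    MultiEventPolicy,
    Result,
    StrategyName,
    StrategyOptions,
    SubjectRecord,
    TargetConditionSpec,
    read_estimand_spec,
    records_from_frame,
)

__all__ = [
    "EngineOptions",
    "ImputationDirective",
    "ValidationIssue",
    "AuditEntry",
    "AuditLog",
    "DiagnosticAccuracyEstimator",
    "apply_estimand",
    "resolve_condition",
    "validate_imputation_plan",
    "strategy_sweep",
    "SWEEP_LABELS",
    "format_sweep_table",
]

REFERENCE_LIMITATION = (
    "the true target condition was classified by a reference standard; using "
    "a reference standard in place of the true condition is always a "
    "limitation of the study-level estimate"
)

ImputationTarget = Literal["index", "reference"]
ImputationScope = Literal[
    "all",
    "diseased",
    "non_diseased",
    "event_affected",
    "event_free",
    "index_positive",
    "index_negative",
]


@dataclass(frozen=True)
class ImputationDirective:
    """A declared intent to impute missing values for a subject subset."""

    target: ImputationTarget
    imputer: str
    scope: ImputationScope = "all"
    event_type: Optional[str] = None


@dataclass(frozen=True)
class ValidationIssue:
    level: Literal["error", "warning"]
    message: str


@dataclass
class EngineOptions:
    """Analysis options orthogonal to the estimand itself."""

    ci_level: float = 0.95
    ci_method: Literal["wilson", "clopper_pearson"] = "wilson"
    inconclusive: InconclusivePolicy = "separate"
    #: what to do with an absent index result not caused by any event:
    #: "error", "exclude_with_warning", or an imputer spec ("constant:negative", ...)
    missing_index: str = "error"
    #: inconclusive/absent reference results under condition_source="reference":
    #: "exclude_with_warning" or "impute_bernoulli"
    reference_missing: Literal["exclude_with_warning", "impute_bernoulli"] = (
        "exclude_with_warning"
    )
    #: prevalence for the bernoulli reference imputation and for ppv/npv
    prevalence: Optional[float] = None
    seed: Optional[int] = None
    imputation_plan: tuple[ImputationDirective, ...] = ()


@dataclass
class AuditEntry:
    """Per-subject trace: which event governed, which strategy fired, why."""

    subject_id: str
    condition: Condition
    governing_event: Optional[str]
    strategy: Optional[str]
    decision: Decision
    source: str
    stratum_membership: Optional[str] = None
    notes: tuple[str, ...] = ()


@dataclass
class AuditLog:
    entries: list[AuditEntry] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)

    def warn_once(self, message: str) -> None:
        if message not in self.warnings:
            self.warnings.append(message)

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "subject_id": e.subject_id,
                    "condition": e.condition.value,
                    "governing_event": e.governing_event,
                    "strategy": e.strategy,
                    "decision": e.decision.value,
                    "source": e.source,
                    "stratum_membership": e.stratum_membership,
                    "notes": list(e.notes),
                }
                for e in self.entries
            ],
            "warnings": list(self.warnings),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


# ---------------------------------------------------------------------------
# validation of the imputation plan against the estimand
# ---------------------------------------------------------------------------


def validate_imputation_plan(
    spec: EstimandSpec, options: Optional[EngineOptions] = None
) -> list[ValidationIssue]:
    """Check the declared imputation directives against the estimand.

    Three combinations are forbidden outright:

    * imputing index results for subjects outside the target principal
      stratum — the stratum of non-occurrence is defined by *not* having the
      event, and event-affected subjects must not be imputed into it;
    * imputing index results for subjects outside the sensitivity
      denominator (healthy subjects) when sensitivity is a requested
      measure;
    * imputing the reference standard for index-positive subjects when the
      positive predictive value is requested — the partial-verification
      setting in which such imputation is most tempting is exactly where it
      biases the estimate.
    """
    options = options or EngineOptions()
    issues: list[ValidationIssue] = []
    ps_event_free = {
        etype
        for etype, es in spec.strategy_map.items()
        if es.strategy is StrategyName.PRINCIPAL_STRATUM
        and es.options.stratum == "event_free"
    }
    for d in options.imputation_plan:
        if d.target == "index" and d.scope in ("all", "event_affected"):
            affected = (
                ps_event_free
                if d.event_type is None
                else ps_event_free & {d.event_type}
            )
            for etype in sorted(affected):
                issues.append(
                    ValidationIssue(
                        "error",
                        f"imputation of index results for subjects affected by "
                        f"'{etype}' conflicts with the principal-stratum "
                        "(event_free) strategy: subjects in whom the event occurs "
                        "must not be imputed into the stratum of non-occurrence",
                    )
                )
        if (
            d.target == "index"
            and d.scope == "non_diseased"
            and "sensitivity" in spec.accuracy_measures
        ):
            issues.append(
                ValidationIssue(
                    "error",
                    "sensitivity is a requested measure: a missing index test "
                    "must not be imputed for healthy (non-diseased) subjects, "
                    "who lie outside the sensitivity denominator",
                )
            )
        if (
            d.target == "reference"
            and d.scope == "index_positive"
            and "ppv" in spec.accuracy_measures
        ):
            issues.append(
                ValidationIssue(
                    "error",
                    "ppv is a requested measure: the reference standard must not "
                    "be imputed for index-positive subjects (partial-verification "
                    "bias)",
                )
            )
    return issues


# ---------------------------------------------------------------------------
# condition resolution (estimand level vs study level)
# ---------------------------------------------------------------------------


def resolve_condition(
    records: Sequence[SubjectRecord],
    source: Literal["true_condition", "reference"],
    options: Optional[EngineOptions] = None,
    rng: Optional[np.random.Generator] = None,
    audit: Optional[AuditLog] = None,
) -> list[SubjectRecord]:
    """Fill ``true_condition`` either directly or via the reference standard.

    With ``source="reference"``, a positive reference maps to diseased and a
    negative one to non-diseased; inconclusive or absent references follow
    the ``reference_missing`` policy (exclusion with a warning, or a seeded
    Bernoulli imputation at a supplied prevalence). A subject left unknown
    is later excluded exactly once, and logged.
    """
    options = options or EngineOptions()
    audit = audit if audit is not None else AuditLog()
    if source == "true_condition":
        return list(records)

    if options.reference_missing == "impute_bernoulli":
        if options.prevalence is None:
            raise SpecValidationError(
                "reference_missing='impute_bernoulli' requires options.prevalence"
            )
        if rng is None:
            rng = np.random.default_rng(options.seed)

    out: list[SubjectRecord] = []
    n_missing = 0
    for rec in records:
        ref = rec.reference_result
        if ref is Result.POSITIVE:
            out.append(rec.with_condition(Condition.DISEASED))
        elif ref is Result.NEGATIVE:
            out.append(rec.with_condition(Condition.NON_DISEASED))
        elif options.reference_missing == "impute_bernoulli":
            cond = (
                Condition.DISEASED
                if rng.random() < options.prevalence  # type: ignore[operator]
                else Condition.NON_DISEASED
            )
            out.append(rec.with_condition(cond))
        else:
            n_missing += 1
            out.append(rec.with_condition(Condition.UNKNOWN))
    if n_missing:
        audit.warn_once(
            f"{n_missing} subject(s) had an inconclusive or absent reference "
            "result and were excluded from the analysis (reference_missing="
            "'exclude_with_warning')"
        )
    return out


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class DiagnosticAccuracyEstimator(BaseEstimator):
    """Apply a diagnostic accuracy estimand to subject-level study data.

    Parameters mirror :class:`EngineOptions`; ``spec`` may be an
    :class:`~diagest.study_data.EstimandSpec`, a mapping, or a path to a
    YAML/JSON estimand file.

    After ``fit``, the report is in ``report_``, the per-subject trace in
    ``audit_``, and point estimates in ``sensitivity_`` / ``specificity_``
    (when requested by the estimand).

    Examples
    --------
    >>> from diagest.fixtures import ct_example_records, load_ct_estimand
    >>> est = DiagnosticAccuracyEstimator(spec=load_ct_estimand())
    >>> est.fit(ct_example_records(event_type="arrhythmical_breathing"))
    ... # doctest: +ELLIPSIS
    DiagnosticAccuracyEstimator(...)
    >>> round(est.sensitivity_, 2)
    0.75
    """

    def __init__(
        self,
        spec: Union[EstimandSpec, dict, str, Path, None] = None,
        ci_level: float = 0.95,
        ci_method: Literal["wilson", "clopper_pearson"] = "wilson",
        inconclusive: InconclusivePolicy = "separate",
        missing_index: str = "error",
        reference_missing: Literal[
            "exclude_with_warning", "impute_bernoulli"
        ] = "exclude_with_warning",
        prevalence: Optional[float] = None,
        seed: Optional[int] = None,
        imputation_plan: tuple[ImputationDirective, ...] = (),
    ) -> None:
        self.spec = spec
        self.ci_level = ci_level
        self.ci_method = ci_method
        self.inconclusive = inconclusive
        self.missing_index = missing_index
        self.reference_missing = reference_missing
        self.prevalence = prevalence
        self.seed = seed
        self.imputation_plan = imputation_plan

    # -- helpers -----------------------------------------------------------

    def _options(self) -> EngineOptions:
        return EngineOptions(
            ci_level=self.ci_level,
            ci_method=self.ci_method,
            inconclusive=self.inconclusive,
            missing_index=self.missing_index,
            reference_missing=self.reference_missing,
            prevalence=self.prevalence,
            seed=self.seed,
            imputation_plan=tuple(self.imputation_plan),
        )

    def _resolve_spec(self) -> EstimandSpec:
        if isinstance(self.spec, EstimandSpec):
            return self.spec
        if isinstance(self.spec, dict):
            return EstimandSpec.model_validate(self.spec)
        if isinstance(self.spec, (str, Path)):
            return read_estimand_spec(self.spec)
        raise SpecValidationError("an estimand spec is required (spec=None)")

    @staticmethod
    def _as_records(X) -> list[SubjectRecord]:
        if isinstance(X, pd.DataFrame):
            return records_from_frame(X.astype(str))
        records = list(X)
        for r in records:
            if not isinstance(r, SubjectRecord):
                raise TypeError(
                    "X must be a DataFrame or a sequence of SubjectRecord, "
                    f"got element of type {type(r).__name__}"
                )
        return records

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "DiagnosticAccuracyEstimator":
        """Run the full estimand pipeline on subject records.

        ``X`` is a sequence of :class:`SubjectRecord` or a string DataFrame
        in the subject-table layout; ``y`` is ignored (the reference
        standard travels inside the records).
        """
        spec = self._resolve_spec()
        options = self._options()
        issues = validate_imputation_plan(spec, options)
        errors = [i for i in issues if i.level == "error"]
        if errors:
            raise SpecValidationError(
                "invalid imputation plan:\n- " + "\n- ".join(i.message for i in errors)
            )

        records = self._as_records(X)
        rng = np.random.default_rng(options.seed)
        audit = AuditLog()
        for i in issues:  # warnings only at this point
            audit.warn_once(i.message)

        kept, n_filtered = _filter_population(records, spec, audit)
        resolved = resolve_condition(
            kept, spec.condition_source, options, rng, audit
        )

        decisions: list[DerivedDecision] = []
        conditions: list[Condition] = []
        strata: list[Optional[bool]] = []  # with-IE flag of the governing event
        for rec in resolved:
            entry = _apply_strategy_map(rec, spec, options, rng, audit)
            decisions.append(
                DerivedDecision(
                    entry.subject_id,
                    entry.decision,
                    entry.source,
                    entry.stratum_membership,
                )
            )
            conditions.append(entry.condition)
            strata.append(entry.governing_event is not None)

        _resolve_missing(decisions, resolved, options, rng, audit)

        still_missing = [
            d.subject_id for d in decisions if d.decision is Decision.NEEDS_IMPUTATION
        ]
        if still_missing:
            raise ImputationError(
                "decisions still need imputation for subject(s): "
                + ", ".join(still_missing)
                + "; configure missing_index or a strategy imputer"
            )

        report = _build_report(
            spec, options, decisions, conditions, strata, len(records), n_filtered, audit
        )

        self.spec_ = spec
        self.report_ = report
        self.audit_ = audit
        self.decisions_ = decisions
        self.n_subjects_ = len(records)
        if "sensitivity" in report.measures:
            self.sensitivity_ = report.measures["sensitivity"].estimate
        if "specificity" in report.measures:
            self.specificity_ = report.measures["specificity"].estimate
        return self

    def score(self, X=None, y=None) -> float:
        """Youden index of the fitted report (sensitivity + specificity - 1)."""
        rep = self.report_
        return (
            rep.measures["sensitivity"].estimate
            + rep.measures["specificity"].estimate
            - 1.0
        )


# ---------------------------------------------------------------------------
# pipeline internals
# ---------------------------------------------------------------------------


def _filter_population(
    records: list[SubjectRecord], spec: EstimandSpec, audit: AuditLog
) -> tuple[list[SubjectRecord], int]:
    """Apply the population attribute's covariate filter (before anything
    else: the population is an estimand attribute, not a post-hoc set)."""
    query = spec.population.filter_query
    if not query:
        return records, 0
    frame = pd.DataFrame(
        [dict(r.covariates) for r in records], index=range(len(records))
    )
    try:
        kept_idx = set(frame.query(query).index)
    except Exception as exc:
        raise SpecValidationError(
            f"population filter query {query!r} failed: {exc}"
        ) from exc
    kept = [r for i, r in enumerate(records) if i in kept_idx]
    n_filtered = len(records) - len(kept)
    if n_filtered:
        audit.warn_once(
            f"{n_filtered} subject(s) outside the estimand population "
            f"(filter: {query!r}) were not analysed"
        )
    return kept, n_filtered


def _apply_strategy_map(
    rec: SubjectRecord,
    spec: EstimandSpec,
    options: EngineOptions,
    rng: np.random.Generator,
    audit: AuditLog,
) -> AuditEntry:
    for ev in rec.occurred_events:
        if ev.event_type not in spec.strategy_map:
            raise SpecValidationError(
                f"subject {rec.subject_id}: event '{ev.event_type}' occurred but "
                "has no strategy in the estimand; every interfering event needs "
                "exactly one strategy"
            )
    governing = resolve_events(rec, spec.multi_event_policy)

    if governing is not None:
        es = spec.strategy_for(governing.event_type)
        decision = apply_strategy(
            rec, governing.event_type, es.strategy, es.options, rng
        )
        entry = AuditEntry(
            subject_id=rec.subject_id,
            condition=rec.true_condition,
            governing_event=governing.event_type,
            strategy=es.strategy.value,
            decision=decision.decision,
            source=decision.source,
            stratum_membership=decision.stratum_membership,
        )
        audit.entries.append(entry)
        return entry

    # no occurred event: passthrough, except that a principal-stratum
    # strategy targeting the event-affected stratum excludes this subject
    ps_affected = [
        etype
        for etype, es in spec.strategy_map.items()
        if es.strategy is StrategyName.PRINCIPAL_STRATUM
        and es.options.stratum == "event_affected"
    ]
    if ps_affected:
        es = spec.strategy_map[ps_affected[0]]
        decision = apply_strategy(
            rec, ps_affected[0], es.strategy, es.options, rng
        )
    else:
        decision = apply_strategy(
            rec, "_none", StrategyName.DIAGNOSTIC_POLICY, StrategyOptions(), rng
        )
        decision.source = "no_event:passthrough"
    entry = AuditEntry(
        subject_id=rec.subject_id,
        condition=rec.true_condition,
        governing_event=None,
        strategy=None,
        decision=decision.decision,
        source=decision.source,
        stratum_membership=decision.stratum_membership,
    )
    audit.entries.append(entry)
    return entry


def _resolve_missing(
    decisions: list[DerivedDecision],
    records: list[SubjectRecord],
    options: EngineOptions,
    rng: np.random.Generator,
    audit: AuditLog,
) -> None:
    """Handle event-unrelated missing results and unknown conditions."""
    by_id = {r.subject_id: r for r in records}
    n_unknown = 0
    for d in decisions:
        rec = by_id[d.subject_id]
        if (
            d.decision is not Decision.EXCLUDED
            and rec.true_condition is Condition.UNKNOWN
        ):
            # unresolved reference: single exclusion even if a strategy would
            # also have excluded the subject
            d.decision = Decision.EXCLUDED
            d.source += "+excluded:unknown_condition"
            n_unknown += 1
            continue
        if d.decision is not Decision.NEEDS_IMPUTATION:
            continue
        policy = options.missing_index
        if policy == "error":
            continue  # reported collectively by the caller
        if policy == "exclude_with_warning":
            d.decision = Decision.EXCLUDED
            d.source += "+excluded:missing_index"
            audit.warn_once(
                "subject(s) with an index result missing for reasons unrelated "
                "to any interfering event were excluded (missing_index="
                "'exclude_with_warning'); this exclusion could introduce bias"
            )
        else:  # an imputer spec
            result = get_imputer(policy)(rec, rng)
            d.decision = Decision(result.value)
            d.source += f"+imputer:{policy}"
    if n_unknown:
        audit.warn_once(
            f"{n_unknown} subject(s) with an unknown condition were excluded"
        )


def _build_report(
    spec: EstimandSpec,
    options: EngineOptions,
    decisions: list[DerivedDecision],
    conditions: list[Condition],
    with_ie: list[bool],
    n_input: int,
    n_filtered: int,
    audit: AuditLog,
) -> AccuracyReport:
    joined = list(zip(decisions, conditions))
    if options.inconclusive == "exclude":
        audit.warn_once(EXCLUSION_BIAS_WARNING)

    measures: dict[str, object] = {}
    breakdowns: dict[str, dict[str, Optional[tuple[int, int]]]] = {}
    for name, fn, target, correct in (
        ("sensitivity", sensitivity, Condition.DISEASED, Decision.POSITIVE),
        ("specificity", specificity, Condition.NON_DISEASED, Decision.NEGATIVE),
    ):
        if name not in spec.accuracy_measures and not (
            {"youden", "lr_positive", "lr_negative", "ppv", "npv"}
            & set(spec.accuracy_measures)
        ):
            continue
        measures[name] = fn(
            joined,
            ci_level=options.ci_level,
            ci_method=options.ci_method,
            inconclusive=options.inconclusive,
        )
        breakdowns[name] = _stratum_breakdown(
            joined, with_ie, target, correct, options.inconclusive
        )

    derived = None
    wants_derived = {"youden", "lr_positive", "lr_negative", "ppv", "npv"} & set(
        spec.accuracy_measures
    )
    if wants_derived:
        prevalence = options.prevalence
        if prevalence is None and {"ppv", "npv"} & wants_derived:
            n_dis = sum(
                1
                for d, c in joined
                if d.decision not in (Decision.EXCLUDED,) and c is Condition.DISEASED
            )
            n_all = sum(1 for d, c in joined if d.decision is not Decision.EXCLUDED)
            prevalence = n_dis / n_all if n_all else None
        derived = derived_measures(
            measures["sensitivity"], measures["specificity"], prevalence
        )

    n_excluded = sum(1 for d in decisions if d.decision is Decision.EXCLUDED)
    n_inconclusive = sum(
        1
        for d in decisions
        if d.decision is Decision.INCONCLUSIVE
        and options.inconclusive in ("separate", "exclude")
    )
    n_included = len(decisions) - n_excluded - n_inconclusive

    limitations = []
    if spec.condition_source == "reference":
        limitations.append(REFERENCE_LIMITATION)

    return AccuracyReport(
        measures=measures,  # type: ignore[arg-type]
        derived=derived,
        breakdowns=breakdowns,
        n_input=n_input,
        n_included=n_included,
        n_excluded=n_excluded,
        n_inconclusive=n_inconclusive,
        n_population_filtered=n_filtered,
        ci_level=options.ci_level,
        ci_method=options.ci_method,
        strategy_labels={
            etype: es.strategy.value for etype, es in spec.strategy_map.items()
        },
        warnings=tuple(audit.warnings),
        limitations=tuple(limitations),
    )


def _stratum_breakdown(
    joined: list[tuple[DerivedDecision, Condition]],
    with_ie: list[bool],
    target: Condition,
    correct: Decision,
    inconclusive: InconclusivePolicy,
) -> dict[str, Optional[tuple[int, int]]]:
    def frac(subset: list[tuple[DerivedDecision, Condition]]):
        num = den = 0
        for d, c in subset:
            if c is not target:
                continue
            dd = d.decision
            if dd is Decision.EXCLUDED:
                continue
            if dd is Decision.INCONCLUSIVE:
                if inconclusive in ("separate", "exclude"):
                    continue
                dd = Decision(inconclusive)
            den += 1
            if dd is correct:
                num += 1
        return None if den == 0 else (num, den)

    without = frac([jc for jc, w in zip(joined, with_ie) if not w])
    with_ = frac([jc for jc, w in zip(joined, with_ie) if w])
    combined = frac(joined)
    return {"without_ie": without, "with_ie": with_, "combined": combined}


def apply_estimand(
    records: Sequence[SubjectRecord],
    spec: Union[EstimandSpec, dict, str, Path],
    options: Optional[EngineOptions] = None,
) -> tuple[AccuracyReport, AuditLog]:
    """Functional wrapper: fit a :class:`DiagnosticAccuracyEstimator`."""
    options = options or EngineOptions()
    est = DiagnosticAccuracyEstimator(
        spec=spec,
        ci_level=options.ci_level,
        ci_method=options.ci_method,
        inconclusive=options.inconclusive,
        missing_index=options.missing_index,
        reference_missing=options.reference_missing,
        prevalence=options.prevalence,
        seed=options.seed,
        imputation_plan=tuple(options.imputation_plan),
    ).fit(records)
    return est.report_, est.audit_


# ---------------------------------------------------------------------------
# strategy sweep (one event type analysed under all eight configurations)
# ---------------------------------------------------------------------------

#: label -> (strategy, options) for the eight standard configurations
SWEEP_CONFIGS: dict[str, EventStrategy] = {
    "DP": EventStrategy(strategy=StrategyName.DIAGNOSTIC_POLICY),
    "HY": EventStrategy(
        strategy=StrategyName.HYPOTHETICAL, options=StrategyOptions(imputer="oracle")
    ),
    "WUM": EventStrategy(strategy=StrategyName.WHILE_UNDER_MONITORING),
    "PS1": EventStrategy(
        strategy=StrategyName.PRINCIPAL_STRATUM,
        options=StrategyOptions(stratum="event_free"),
    ),
    "PS2": EventStrategy(
        strategy=StrategyName.PRINCIPAL_STRATUM,
        options=StrategyOptions(stratum="event_affected"),
    ),
    "IE+": EventStrategy(
        strategy=StrategyName.INDICATIVE_EVENT,
        options=StrategyOptions(fixed_result="positive"),
    ),
    "IE-": EventStrategy(
        strategy=StrategyName.INDICATIVE_EVENT,
        options=StrategyOptions(fixed_result="negative"),
    ),
    "SB": EventStrategy(strategy=StrategyName.SETBACK),
}

SWEEP_LABELS = tuple(SWEEP_CONFIGS)


def strategy_sweep(
    records: Sequence[SubjectRecord],
    event_type: str,
    options: Optional[EngineOptions] = None,
    labels: Sequence[str] = SWEEP_LABELS,
) -> dict[str, AccuracyReport]:
    """Analyse the same data under each standard strategy configuration.

    The hypothetical row uses the oracle imputer (stored counterfactuals)
    and the while-under-monitoring row the stored pre-event partial results,
    exactly the per-subject information a strategy-comparison table assumes.
    """
    reports: dict[str, AccuracyReport] = {}
    for label in labels:
        es = SWEEP_CONFIGS[label]
        spec = EstimandSpec(
            target_condition=TargetConditionSpec(label="target condition"),
            index_test=IndexTestSpec(rule="index test"),
            accuracy_measures=["sensitivity", "specificity"],
            strategy_map={event_type: es},
            multi_event_policy=MultiEventPolicy(),
            condition_source="true_condition",
        )
        report, _ = apply_estimand(records, spec, options)
        reports[label] = report
    return reports
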