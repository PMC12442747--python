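"""The six interfering-event handling strategies as pure decision transforms.

Each ``apply_*`` function maps ``(record, event_type, options)`` to a
:class:`~diagest.study_data.DerivedDecision`. A record whose governing event
did not occur passes its observed index result through unchanged under every
strategy — except the principal-stratum strategy targeting the
event-affected stratum, which excludes such a record from the analysis set.

The diagnostic-policy, indicative-event, and setback strategies form a
*composite test* family: the final decision is a pure function g(I, E) of
the index result I and the event occurrence E (plus, for setback, the true
condition). :func:`composite_decision` exposes that truth-table view.

Counts-only workflows (a 2x2x2 table instead of subject records) are
supported for every strategy that is a pure function of
(disease state, IE occurrence, result); see :func:`accuracy_from_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import (
    EventResolutionError,
    ImputationError,
    StrategyApplicabilityError,
)
from .imputers import get_imputer
from .study_data import (
    Condition,
    Decision,
    DerivedDecision,
    EventOccurrence,
    MultiEventPolicy,
    Result,
    StratifiedCounts,
    StrategyName,
    StrategyOptions,
    SubjectRecord,
)

__all__ = [
    "apply_diagnostic_policy",
    "apply_indicative_event",
    "apply_setback",
    "apply_hypothetical",
    "apply_while_under_monitoring",
    "apply_principal_stratum",
    "apply_strategy",
    "resolve_events",
    "composite_decision",
    "FractionCell",
    "CountsAccuracy",
    "accuracy_from_counts",
    "register_partial_rule",
    "COMPOSITE_STRATEGIES",
]

#: strategies whose decision is a pure function g(I, E) (+ condition for setback)
COMPOSITE_STRATEGIES = frozenset(
    {
        StrategyName.DIAGNOSTIC_POLICY,
        StrategyName.INDICATIVE_EVENT,
        StrategyName.SETBACK,
    }
)

_RESULT_TO_DECISION = {
    Result.POSITIVE: Decision.POSITIVE,
    Result.NEGATIVE: Decision.NEGATIVE,
    Result.INCONCLUSIVE: Decision.INCONCLUSIVE,
}

# rules mapping pre-event data to a decision, for while-under-monitoring
_PARTIAL_RULES: dict[str, Callable[[SubjectRecord], Result]] = {}


def register_partial_rule(name: str, rule: Callable[[SubjectRecord], Result]) -> None:
    """Register a named rule deriving a decision from pre-event measurements."""
    _PARTIAL_RULES[name] = rule


def _passthrough(record: SubjectRecord, source: str) -> DerivedDecision:
    """No-event behaviour shared by every strategy: use the observed result."""
    if record.index_result is Result.ABSENT:
        # missingness unrelated to the event (e.g. a lost sample); the
        # engine's missing-data options decide, never the IE strategy
        return DerivedDecision(
            record.subject_id, Decision.NEEDS_IMPUTATION, source=f"{source}:missing_without_event"
        )
    return DerivedDecision(
        record.subject_id, _RESULT_TO_DECISION[record.index_result], source=source
    )


def _impute(
    record: SubjectRecord,
    imputer_spec: str,
    rng: Optional[np.random.Generator],
    source: str,
) -> DerivedDecision:
    result = get_imputer(imputer_spec)(record, rng)
    if result not in (Result.POSITIVE, Result.NEGATIVE):
        raise ImputationError(
            f"subject {record.subject_id}: imputer '{imputer_spec}' must return "
            f"positive or negative, got {result.value}"
        )
    return DerivedDecision(
        record.subject_id,
        _RESULT_TO_DECISION[result],
        source=f"{source}+imputer:{imputer_spec}",
    )


def apply_diagnostic_policy(
    record: SubjectRecord,
    event_type: str,
    options: Optional[StrategyOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Use the observed index result, ignoring the event's occurrence.

    The only complication is an event that left no test decision: then an
    imputation rule must be configured, because an event that consistently
    yields non-existent decisions cannot be handled by this strategy at all.
    """
    options = options or StrategyOptions()
    occurred = record.has_event(event_type)
    if record.index_result is Result.ABSENT and occurred:
        if options.imputer is None:
            raise StrategyApplicabilityError(
                f"subject {record.subject_id}: the event left no test decision and "
                "the diagnostic-policy strategy has no imputer configured; an event "
                "that consistently yields non-existent decisions is not suitable "
                "for this strategy"
            )
        return _impute(record, options.imputer, rng, "diagnostic_policy")
    return _passthrough(record, "diagnostic_policy")


def apply_indicative_event(
    record: SubjectRecord,
    event_type: str,
    options: StrategyOptions,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """The event itself dictates a fixed positive or negative decision.

    The event is treated as an additional test criterion: its occurrence
    always yields ``options.fixed_result``, whatever the observed index
    result was (even if none exists).
    """
    if options.fixed_result is None:
        raise StrategyApplicabilityError(
            "indicative_event requires the fixed_result option"
        )
    if record.has_event(event_type):
        return DerivedDecision(
            record.subject_id,
            Decision(options.fixed_result),
            source=f"indicative_event:{options.fixed_result}",
        )
    return _passthrough(record, "indicative_event")


def apply_setback(
    record: SubjectRecord,
    event_type: str,
    options: Optional[StrategyOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Penalize the event: its occurrence forces a misclassification.

    The decision is set to the opposite of the true condition — negative for
    diseased subjects, positive for non-diseased ones — so accuracy degrades
    as the event frequency rises. Knowing the true condition is therefore a
    prerequisite; when it is unknown, a reference imputer must be configured.
    """
    options = options or StrategyOptions()
    if not record.has_event(event_type):
        return _passthrough(record, "setback")
    condition = record.true_condition
    source = "setback"
    if condition is Condition.UNKNOWN:
        if options.imputer is None:
            raise StrategyApplicabilityError(
                f"subject {record.subject_id}: setback needs the true condition "
                "(to assign the opposite result) or a reference imputer"
            )
        imputed = get_imputer(options.imputer)(record, rng)
        condition = (
            Condition.DISEASED if imputed is Result.POSITIVE else Condition.NON_DISEASED
        )
        source = f"setback+imputer:{options.imputer}"
    decision = (
        Decision.NEGATIVE if condition is Condition.DISEASED else Decision.POSITIVE
    )
    return DerivedDecision(record.subject_id, decision, source=source)


def apply_hypothetical(
    record: SubjectRecord,
    event_type: str,
    options: StrategyOptions,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Estimate accuracy in a scenario where the event cannot occur.

    Affected results are replaced by a prediction of the result had the
    event not occurred; the configured imputer supplies that prediction
    (on simulated data the ``oracle`` imputer reads the stored
    counterfactual result).
    """
    if options.imputer is None:
        raise StrategyApplicabilityError("hypothetical requires the imputer option")
    if record.has_event(event_type):
        return _impute(record, options.imputer, rng, "hypothetical")
    return _passthrough(record, "hypothetical")


def apply_while_under_monitoring(
    record: SubjectRecord,
    event_type: str,
    options: Optional[StrategyOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Decide from measurements collected before the event only.

    Post-event values are simply not part of the index test under this
    estimand — they are not considered missing. Requires a stored pre-event
    partial result (or a registered ``partial_rule``) whenever the event
    occurred; the index test must have an observation period for this
    strategy to make sense.
    """
    options = options or StrategyOptions()
    if not record.has_event(event_type):
        return _passthrough(record, "while_under_monitoring")
    if record.partial_result is not Result.ABSENT:
        return DerivedDecision(
            record.subject_id,
            _RESULT_TO_DECISION[record.partial_result],
            source="while_under_monitoring:partial_result",
        )
    if options.partial_rule is not None:
        try:
            rule = _PARTIAL_RULES[options.partial_rule]
        except KeyError:
            raise StrategyApplicabilityError(
                f"unknown partial rule '{options.partial_rule}'"
            ) from None
        result = rule(record)
        if result not in (Result.POSITIVE, Result.NEGATIVE):
            raise StrategyApplicabilityError(
                f"partial rule '{options.partial_rule}' must return positive or negative"
            )
        return DerivedDecision(
            record.subject_id,
            _RESULT_TO_DECISION[result],
            source=f"while_under_monitoring:rule:{options.partial_rule}",
        )
    raise StrategyApplicabilityError(
        f"subject {record.subject_id}: while-under-monitoring needs a pre-event "
        "partial result or a partial_rule; the index test must have an "
        "observation period preceding the event"
    )


def apply_principal_stratum(
    record: SubjectRecord,
    event_type: str,
    options: StrategyOptions,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Evaluate accuracy inside the stratum in which the event would (not) occur.

    Stratum membership is taken from the observed occurrence. Records outside
    the target stratum are excluded from the analysis set; records inside it
    keep their observed result.
    """
    if options.stratum is None:
        raise StrategyApplicabilityError("principal_stratum requires the stratum option")
    membership = "event_affected" if record.has_event(event_type) else "event_free"
    if membership != options.stratum:
        return DerivedDecision(
            record.subject_id,
            Decision.EXCLUDED,
            source=f"principal_stratum:{options.stratum}",
            stratum_membership=membership,
        )
    out = _passthrough(record, f"principal_stratum:{options.stratum}")
    out.stratum_membership = membership
    return out


_APPLIERS = {
    StrategyName.DIAGNOSTIC_POLICY: apply_diagnostic_policy,
    StrategyName.INDICATIVE_EVENT: apply_indicative_event,
    StrategyName.SETBACK: apply_setback,
    StrategyName.HYPOTHETICAL: apply_hypothetical,
    StrategyName.WHILE_UNDER_MONITORING: apply_while_under_monitoring,
    StrategyName.PRINCIPAL_STRATUM: apply_principal_stratum,
}


def apply_strategy(
    record: SubjectRecord,
    event_type: str,
    strategy: StrategyName,
    options: Optional[StrategyOptions] = None,
    rng: Optional[np.random.Generator] = None,
) -> DerivedDecision:
    """Dispatch to the named strategy's ``apply_*`` function."""
    return _APPLIERS[StrategyName(strategy)](
        record, event_type, options or StrategyOptions(), rng
    )


# ---------------------------------------------------------------------------
# multi-event resolution
# ---------------------------------------------------------------------------


def resolve_events(
    record: SubjectRecord, policy: Optional[MultiEventPolicy] = None
) -> Optional[EventOccurrence]:
    """Reduce a record's occurred events to the single governing one.

    The framework assumes one interfering event per subject; when several
    occurred, either the first in time governs (``first_event``) or the
    highest-priority type does (``priority``). Ties are an error — there is
    no silent tie-break.
    """
    policy = policy or MultiEventPolicy()
    occurred = [e for e in record.events if e.occurred]
    if not occurred:
        return None
    if len(occurred) == 1:
        return occurred[0]

    if policy.policy == "first_event":
        if any(e.time is None for e in occurred):
            raise EventResolutionError(
                f"subject {record.subject_id}: first_event policy needs a time on "
                "every occurred event"
            )
        times = sorted(e.time for e in occurred)  # type: ignore[type-var]
        if times[0] == times[1]:
            raise EventResolutionError(
                f"subject {record.subject_id}: two events share the earliest time "
                f"({times[0]}); cannot pick a governing event"
            )
        return min(occurred, key=lambda e: e.time)  # type: ignore[arg-type, return-value]

    order = {etype: i for i, etype in enumerate(policy.priority)}
    missing = [e.event_type for e in occurred if e.event_type not in order]
    if missing:
        raise EventResolutionError(
            f"subject {record.subject_id}: event type(s) {sorted(set(missing))} "
            "are not in the priority order"
        )
    ranks = sorted(order[e.event_type] for e in occurred)
    if ranks[0] == ranks[1]:
        raise EventResolutionError(
            f"subject {record.subject_id}: two occurred events share the highest "
            "priority; cannot pick a governing event"
        )
    return min(occurred, key=lambda e: order[e.event_type])


# ---------------------------------------------------------------------------
# composite-test view g(I, E)
# ---------------------------------------------------------------------------


def composite_decision(
    index_result: Result,
    event_occurred: bool,
    strategy: StrategyName,
    options: Optional[StrategyOptions] = None,
    condition: Condition = Condition.UNKNOWN,
) -> Decision:
    """The composite test g(I, E) for the diagnostic-policy / indicative-event
    / setback family, as a pure truth-table function.

    ``condition`` is required context for setback (its output depends on the
    true state, not on I). Matches the corresponding ``apply_*`` on a minimal
    record.
    """
    strategy = StrategyName(strategy)
    if strategy not in COMPOSITE_STRATEGIES:
        raise StrategyApplicabilityError(
            f"'{strategy.value}' is not a composite-test strategy "
            f"(composite family: diagnostic_policy, indicative_event, setback)"
        )
    record = SubjectRecord(
        subject_id="_composite",
        true_condition=condition,
        index_result=index_result,
        events=(EventOccurrence("_e"),) if event_occurred else (),
    )
    return apply_strategy(record, "_e", strategy, options).decision


# ---------------------------------------------------------------------------
# counts-only strategy application (the shape of a strategy-comparison table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionCell:
    """A correct/total fraction for one table cell."""

    correct: int
    total: int

    @property
    def estimate(self) -> float:
        if self.total == 0:
            raise ZeroDivisionError("empty cell")
        return self.correct / self.total

    def __str__(self) -> str:
        return f"{self.correct}/{self.total}"


@dataclass(frozen=True)
class CountsAccuracy:
    """Per-stratum and combined correct-decision fractions under one strategy."""

    strategy: str
    sens_without_ie: Optional[FractionCell]
    sens_with_ie: Optional[FractionCell]
    sens_combined: FractionCell
    spec_without_ie: Optional[FractionCell]
    spec_with_ie: Optional[FractionCell]
    spec_combined: FractionCell

    @property
    def sensitivity(self) -> float:
        return self.sens_combined.estimate

    @property
    def specificity(self) -> float:
        return self.spec_combined.estimate


def _combine(a: Optional[FractionCell], b: Optional[FractionCell]) -> FractionCell:
    cells = [c for c in (a, b) if c is not None]
    return FractionCell(sum(c.correct for c in cells), sum(c.total for c in cells))


def accuracy_from_counts(
    counts: StratifiedCounts,
    strategy: StrategyName,
    options: Optional[StrategyOptions] = None,
    *,
    diseased_with_ie_correct: Optional[int] = None,
    healthy_with_ie_correct: Optional[int] = None,
) -> CountsAccuracy:
    """Apply a strategy directly to a 2x2x2 count table.

    Diagnostic policy, indicative event, setback, and principal stratum are
    pure functions of the cells. The hypothetical and while-under-monitoring
    strategies depend on per-subject information the table does not carry, so
    the corrected numbers of correct with-IE decisions must be supplied
    (``diseased_with_ie_correct`` positives among the diseased with-IE cell,
    ``healthy_with_ie_correct`` negatives among the healthy with-IE cell).
    """
    options = options or StrategyOptions()
    strategy = StrategyName(strategy)
    d0, d1 = counts.diseased_without_ie, counts.diseased_with_ie
    h0, h1 = counts.healthy_without_ie, counts.healthy_with_ie

    sens0 = FractionCell(d0.positive, d0.conclusive)
    spec0 = FractionCell(h0.negative, h0.conclusive)
    n_d1, n_h1 = d1.conclusive, h1.conclusive
    label = strategy.value

    if strategy is StrategyName.DIAGNOSTIC_POLICY:
        sens1 = FractionCell(d1.positive, n_d1)
        spec1 = FractionCell(h1.negative, n_h1)
    elif strategy is StrategyName.INDICATIVE_EVENT:
        if options.fixed_result is None:
            raise StrategyApplicabilityError(
                "indicative_event requires the fixed_result option"
            )
        # with-IE subjects also count the absent results: the event itself
        # decides, whether or not a test decision exists
        n_d1, n_h1 = d1.total, h1.total
        if options.fixed_result == "positive":
            sens1, spec1 = FractionCell(n_d1, n_d1), FractionCell(0, n_h1)
        else:
            sens1, spec1 = FractionCell(0, n_d1), FractionCell(n_h1, n_h1)
        label = f"indicative_event:{options.fixed_result}"
    elif strategy is StrategyName.SETBACK:
        n_d1, n_h1 = d1.total, h1.total
        sens1, spec1 = FractionCell(0, n_d1), FractionCell(0, n_h1)
    elif strategy is StrategyName.PRINCIPAL_STRATUM:
        if options.stratum is None:
            raise StrategyApplicabilityError(
                "principal_stratum requires the stratum option"
            )
        label = f"principal_stratum:{options.stratum}"
        if options.stratum == "event_free":
            return CountsAccuracy(label, sens0, None, sens0, spec0, None, spec0)
        sens1 = FractionCell(d1.positive, n_d1)
        spec1 = FractionCell(h1.negative, n_h1)
        return CountsAccuracy(label, None, sens1, sens1, None, spec1, spec1)
    elif strategy in (StrategyName.HYPOTHETICAL, StrategyName.WHILE_UNDER_MONITORING):
        if diseased_with_ie_correct is None or healthy_with_ie_correct is None:
            raise StrategyApplicabilityError(
                f"{strategy.value} on counts needs corrected with-IE correct counts "
                "(it is not a pure function of the 2x2x2 cells)"
            )
        n_d1, n_h1 = d1.total, h1.total
        sens1 = FractionCell(diseased_with_ie_correct, n_d1)
        spec1 = FractionCell(healthy_with_ie_correct, n_h1)
    else:  # pragma: no cover - enum is exhaustive
        raise StrategyApplicabilityError(strategy.value)

    return CountsAccuracy(
        label,
        sens0,
        sens1,
        _combine(sens0, sens1),
        spec0,
        spec1,
        _combine(spec0, spec1),
    )
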