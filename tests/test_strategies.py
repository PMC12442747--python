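"""Strategy truth tables, event resolution, and counts-level identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diagest.errors import (
    EventResolutionError,
    ImputationError,
    StrategyApplicabilityError,
)
from diagest.strategies import (
    COMPOSITE_STRATEGIES,
    accuracy_from_counts,
    apply_strategy,
    composite_decision,
    resolve_events,
)
from diagest.study_data import (
    Condition,
    Decision,
    EventOccurrence,
    MultiEventPolicy,
    Result,
    StrategyName,
    StrategyOptions,
    SubjectRecord,
)

from conftest import random_counts


def rec(
    condition=Condition.DISEASED,
    result=Result.POSITIVE,
    ie=True,
    partial=Result.ABSENT,
    counterfactual=Result.ABSENT,
):
    return SubjectRecord(
        subject_id="t1",
        true_condition=condition,
        index_result=result,
        events=(EventOccurrence("ie"),) if ie else (),
        partial_result=partial,
        counterfactual_result=counterfactual,
    )


class TestDiagnosticPolicy:
    def test_observed_result_used_despite_event(self):
        d = apply_strategy(rec(), "ie", StrategyName.DIAGNOSTIC_POLICY)
        assert d.decision is Decision.POSITIVE

    def test_absent_with_event_and_no_imputer_is_applicability_error(self):
        with pytest.raises(StrategyApplicabilityError, match="not suitable"):
            apply_strategy(rec(result=Result.ABSENT), "ie", StrategyName.DIAGNOSTIC_POLICY)

    def test_absent_with_event_routes_to_imputer(self):
        d = apply_strategy(
            rec(result=Result.ABSENT),
            "ie",
            StrategyName.DIAGNOSTIC_POLICY,
            StrategyOptions(imputer="constant:positive"),
        )
        assert d.decision is Decision.POSITIVE
        assert "imputer:constant:positive" in d.source


class TestIndicativeEvent:
    @pytest.mark.parametrize("result", list(Result))
    def test_event_forces_fixed_result_whatever_was_observed(self, result):
        d = apply_strategy(
            rec(result=result),
            "ie",
            StrategyName.INDICATIVE_EVENT,
            StrategyOptions(fixed_result="positive"),
        )
        assert d.decision is Decision.POSITIVE

    def test_no_event_passthrough_ignores_fixed_result(self):
        d = apply_strategy(
            rec(result=Result.POSITIVE, ie=False),
            "ie",
            StrategyName.INDICATIVE_EVENT,
            StrategyOptions(fixed_result="negative"),
        )
        assert d.decision is Decision.POSITIVE


class TestSetback:
    def test_diseased_with_event_forced_negative(self):
        d = apply_strategy(rec(), "ie", StrategyName.SETBACK)
        assert d.decision is Decision.NEGATIVE

    def test_healthy_with_event_forced_positive(self):
        d = apply_strategy(
            rec(condition=Condition.NON_DISEASED, result=Result.NEGATIVE),
            "ie",
            StrategyName.SETBACK,
        )
        assert d.decision is Decision.POSITIVE

    def test_no_event_passthrough(self):
        d = apply_strategy(rec(ie=False), "ie", StrategyName.SETBACK)
        assert d.decision is Decision.POSITIVE

    def test_unknown_condition_without_imputer_raises(self):
        with pytest.raises(StrategyApplicabilityError, match="true condition"):
            apply_strategy(rec(condition=Condition.UNKNOWN), "ie", StrategyName.SETBACK)

    def test_unknown_condition_with_reference_imputer(self):
        d = apply_strategy(
            rec(condition=Condition.UNKNOWN),
            "ie",
            StrategyName.SETBACK,
            StrategyOptions(imputer="constant:positive"),  # imputed diseased
        )
        assert d.decision is Decision.NEGATIVE


class TestHypothetical:
    def test_oracle_returns_counterfactual(self):
        d = apply_strategy(
            rec(result=Result.NEGATIVE, counterfactual=Result.POSITIVE),
            "ie",
            StrategyName.HYPOTHETICAL,
            StrategyOptions(imputer="oracle"),
        )
        assert d.decision is Decision.POSITIVE

    def test_oracle_without_counterfactual_fails_loudly(self):
        with pytest.raises(ImputationError, match="counterfactual"):
            apply_strategy(
                rec(), "ie", StrategyName.HYPOTHETICAL, StrategyOptions(imputer="oracle")
            )

    def test_degenerate_constant_imputer(self):
        d = apply_strategy(
            rec(result=Result.NEGATIVE),
            "ie",
            StrategyName.HYPOTHETICAL,
            StrategyOptions(imputer="bernoulli:1.0"),
            rng=np.random.default_rng(0),
        )
        assert d.decision is Decision.POSITIVE

    def test_no_event_passthrough(self):
        d = apply_strategy(
            rec(ie=False), "ie", StrategyName.HYPOTHETICAL, StrategyOptions(imputer="oracle")
        )
        assert d.decision is Decision.POSITIVE


class TestWhileUnderMonitoring:
    def test_partial_result_used_when_event_occurred(self):
        d = apply_strategy(
            rec(result=Result.POSITIVE, partial=Result.NEGATIVE),
            "ie",
            StrategyName.WHILE_UNDER_MONITORING,
        )
        assert d.decision is Decision.NEGATIVE

    def test_missing_partial_names_observation_period(self):
        with pytest.raises(StrategyApplicabilityError, match="observation period"):
            apply_strategy(rec(), "ie", StrategyName.WHILE_UNDER_MONITORING)

    def test_matches_diagnostic_policy_when_partials_equal_observed(self, ct_records):
        from dataclasses import replace

        same = [
            replace(r, partial_result=r.index_result) if r.occurred_events else r
            for r in ct_records
        ]
        for r in same:
            wum = apply_strategy(r, "coughing", StrategyName.WHILE_UNDER_MONITORING)
            dp = apply_strategy(r, "coughing", StrategyName.DIAGNOSTIC_POLICY)
            assert wum.decision == dp.decision


class TestPrincipalStratum:
    def test_event_free_stratum_excludes_affected(self):
        d = apply_strategy(
            rec(), "ie", StrategyName.PRINCIPAL_STRATUM, StrategyOptions(stratum="event_free")
        )
        assert d.decision is Decision.EXCLUDED
        assert d.stratum_membership == "event_affected"

    def test_event_free_passthrough_for_unaffected(self):
        d = apply_strategy(
            rec(ie=False),
            "ie",
            StrategyName.PRINCIPAL_STRATUM,
            StrategyOptions(stratum="event_free"),
        )
        assert d.decision is Decision.POSITIVE

    def test_fixture_analysis_set_sizes(self, ct_records):
        for stratum, expect_d, expect_h in (
            ("event_free", 16, 120),
            ("event_affected", 24, 40),
        ):
            kept = [
                r
                for r in ct_records
                if apply_strategy(
                    r,
                    "coughing",
                    StrategyName.PRINCIPAL_STRATUM,
                    StrategyOptions(stratum=stratum),
                ).decision
                is not Decision.EXCLUDED
            ]
            n_d = sum(1 for r in kept if r.true_condition is Condition.DISEASED)
            assert (n_d, len(kept) - n_d) == (expect_d, expect_h)


class TestResolveEvents:
    def test_first_event_picks_earliest(self):
        r = SubjectRecord(
            subject_id="s",
            index_result=Result.POSITIVE,
            events=(
                EventOccurrence("A", time=2.0),
                EventOccurrence("B", time=1.0),
            ),
        )
        gov = resolve_events(r, MultiEventPolicy(policy="first_event"))
        assert gov.event_type == "B"

    def test_no_occurred_events_gives_none(self):
        r = SubjectRecord(subject_id="s", index_result=Result.POSITIVE)
        assert resolve_events(r) is None

    def test_single_event_needs_no_time(self):
        r = SubjectRecord(
            subject_id="s",
            index_result=Result.POSITIVE,
            events=(EventOccurrence("A"),),
        )
        assert resolve_events(r).event_type == "A"

    def test_missing_times_with_multiple_events_raise(self):
        r = SubjectRecord(
            subject_id="s",
            index_result=Result.POSITIVE,
            events=(EventOccurrence("A", time=1.0), EventOccurrence("B")),
        )
        with pytest.raises(EventResolutionError, match="time"):
            resolve_events(r, MultiEventPolicy(policy="first_event"))

    def test_time_tie_is_an_error_not_a_silent_pick(self):
        r = SubjectRecord(
            subject_id="s",
            index_result=Result.POSITIVE,
            events=(EventOccurrence("A", time=1.0), EventOccurrence("B", time=1.0)),
        )
        with pytest.raises(EventResolutionError, match="earliest"):
            resolve_events(r, MultiEventPolicy(policy="first_event"))

    def test_priority_order_selected_event_maximizes_order(self):
        # brute force over all orderings of up to 4 event types: the chosen
        # event is always the occurred one appearing first in the order
        types = ["A", "B", "C", "D"]
        for k in (2, 3, 4):
            for perm in itertools.permutations(types[:k]):
                occurred = types[:k]
                r = SubjectRecord(
                    subject_id="s",
                    index_result=Result.POSITIVE,
                    events=tuple(EventOccurrence(t) for t in occurred),
                )
                gov = resolve_events(
                    r, MultiEventPolicy(policy="priority", priority=list(perm))
                )
                expected = min(occurred, key=lambda t: perm.index(t))
                assert gov.event_type == expected

    def test_priority_requires_total_order(self):
        r = SubjectRecord(
            subject_id="s",
            index_result=Result.POSITIVE,
            events=(EventOccurrence("A"), EventOccurrence("X")),
        )
        with pytest.raises(EventResolutionError, match="priority"):
            resolve_events(r, MultiEventPolicy(policy="priority", priority=["A", "B"]))


class TestCompositeDecision:
    def test_truth_tables_match_apply_functions(self):
        configs = [
            (StrategyName.DIAGNOSTIC_POLICY, StrategyOptions(imputer="constant:negative")),
            (StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="positive")),
            (StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="negative")),
            (StrategyName.SETBACK, StrategyOptions()),
        ]
        for strategy, options in configs:
            for result in Result:
                for occurred in (False, True):
                    g = composite_decision(
                        result, occurred, strategy, options, condition=Condition.DISEASED
                    )
                    direct = apply_strategy(
                        rec(result=result, ie=occurred), "ie", strategy, options
                    )
                    assert g == direct.decision, (strategy, result, occurred)

    def test_non_composite_strategy_rejected(self):
        with pytest.raises(StrategyApplicabilityError, match="composite"):
            composite_decision(
                Result.POSITIVE,
                True,
                StrategyName.HYPOTHETICAL,
                StrategyOptions(imputer="oracle"),
            )

    def test_composite_family_membership(self):
        assert StrategyName.PRINCIPAL_STRATUM not in COMPOSITE_STRATEGIES
        assert StrategyName.DIAGNOSTIC_POLICY in COMPOSITE_STRATEGIES


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_no_event_passthrough_property(seed):
    """Any record without occurred events keeps its observed result under
    every strategy except exclusion by the event-affected principal stratum."""
    rng = np.random.default_rng(seed)
    results = [Result.POSITIVE, Result.NEGATIVE, Result.INCONCLUSIVE]
    conditions = [Condition.DISEASED, Condition.NON_DISEASED]
    r = rec(
        condition=conditions[rng.integers(2)],
        result=results[rng.integers(3)],
        ie=False,
    )
    configs = [
        (StrategyName.DIAGNOSTIC_POLICY, StrategyOptions()),
        (StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="positive")),
        (StrategyName.SETBACK, StrategyOptions()),
        (StrategyName.HYPOTHETICAL, StrategyOptions(imputer="oracle")),
        (StrategyName.WHILE_UNDER_MONITORING, StrategyOptions()),
        (StrategyName.PRINCIPAL_STRATUM, StrategyOptions(stratum="event_free")),
    ]
    for strategy, options in configs:
        d = apply_strategy(r, "ie", strategy, options)
        assert d.decision.value == r.index_result.value
    d = apply_strategy(
        r, "ie", StrategyName.PRINCIPAL_STRATUM, StrategyOptions(stratum="event_affected")
    )
    assert d.decision is Decision.EXCLUDED


class TestCountsAccuracy:
    def test_fixture_diagnostic_policy(self, ct_counts):
        ca = accuracy_from_counts(ct_counts, StrategyName.DIAGNOSTIC_POLICY)
        assert (ca.sens_combined.correct, ca.sens_combined.total) == (28, 40)
        assert (ca.spec_combined.correct, ca.spec_combined.total) == (144, 160)

    def test_hypothetical_on_counts_needs_corrected_cells(self, ct_counts):
        with pytest.raises(StrategyApplicabilityError, match="corrected"):
            accuracy_from_counts(ct_counts, StrategyName.HYPOTHETICAL)
        ca = accuracy_from_counts(
            ct_counts,
            StrategyName.HYPOTHETICAL,
            diseased_with_ie_correct=18,
            healthy_with_ie_correct=37,
        )
        assert ca.sensitivity == 0.75
        assert ca.spec_combined.correct == 147

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_identities_on_random_tables(self, seed):
        """Setback equals indicative-negative for sensitivity and
        indicative-positive for specificity; diagnostic policy is the exact
        stratum-weighted mixture of the two principal strata."""
        counts = random_counts(np.random.default_rng(seed))
        sb = accuracy_from_counts(counts, StrategyName.SETBACK)
        ie_pos = accuracy_from_counts(
            counts, StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="positive")
        )
        ie_neg = accuracy_from_counts(
            counts, StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="negative")
        )
        assert sb.sens_combined == ie_neg.sens_combined
        assert sb.spec_combined == ie_pos.spec_combined

        dp = accuracy_from_counts(counts, StrategyName.DIAGNOSTIC_POLICY)
        ps1 = accuracy_from_counts(
            counts, StrategyName.PRINCIPAL_STRATUM, StrategyOptions(stratum="event_free")
        )
        ps2 = accuracy_from_counts(
            counts, StrategyName.PRINCIPAL_STRATUM, StrategyOptions(stratum="event_affected")
        )
        for measure in ("sensitivity", "specificity"):
            n1 = getattr(ps1, f"{'sens' if measure[2] == 'n' else 'spec'}_combined")
            n2 = getattr(ps2, f"{'sens' if measure[2] == 'n' else 'spec'}_combined")
            total = n1.total + n2.total
            mixture = (n1.total * n1.estimate + n2.total * n2.estimate) / total
            assert getattr(dp, measure) == pytest.approx(mixture, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_ordering_chain_on_random_tables(self, seed):
        """indicative-positive >= diagnostic policy >= setback for sensitivity,
        and the mirror chain with indicative-negative for specificity."""
        counts = random_counts(np.random.default_rng(seed))
        dp = accuracy_from_counts(counts, StrategyName.DIAGNOSTIC_POLICY)
        sb = accuracy_from_counts(counts, StrategyName.SETBACK)
        ie_pos = accuracy_from_counts(
            counts, StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="positive")
        )
        ie_neg = accuracy_from_counts(
            counts, StrategyName.INDICATIVE_EVENT, StrategyOptions(fixed_result="negative")
        )
        assert ie_pos.sensitivity >= dp.sensitivity >= sb.sensitivity
        assert ie_neg.specificity >= dp.specificity >= sb.specificity
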