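"""Estimand engine: pipeline, sweep, condition resolution, validation rules."""

import numpy as np
import pytest

from diagest.engine import (
    DiagnosticAccuracyEstimator,
    EngineOptions,
    ImputationDirective,
    apply_estimand,
    resolve_condition,
    strategy_sweep,
    validate_imputation_plan,
)
from diagest.errors import ImputationError, SpecValidationError
from diagest.fixtures import ct_example_records, load_ct_estimand
from diagest.study_data import (
    Condition,
    EventOccurrence,
    Result,
    SubjectRecord,
    records_to_frame,
)

from conftest import make_spec

#: the strategy-comparison reference for the worked example:
#: label -> (sens numerator, sens denominator, spec numerator, spec denominator)
SWEEP_EXPECTED = {
    "DP": (28, 40, 144, 160),
    "HY": (30, 40, 147, 160),
    "WUM": (24, 40, 138, 160),
    "PS1": (12, 16, 110, 120),
    "PS2": (16, 24, 34, 40),
    "IE+": (36, 40, 110, 160),
    "IE-": (12, 40, 150, 160),
    "SB": (12, 40, 110, 160),
}


class TestStrategySweep:
    def test_fixture_reproduces_all_eight_rows(self, ct_records):
        reports = strategy_sweep(ct_records, "coughing")
        for label, (sk, sn, pk, pn) in SWEEP_EXPECTED.items():
            sens = reports[label].measures["sensitivity"]
            spec = reports[label].measures["specificity"]
            assert (sens.numerator, sens.denominator) == (sk, sn), label
            assert (spec.numerator, spec.denominator) == (pk, pn), label

    def test_stratum_breakdowns_match_table_cells(self, ct_records):
        reports = strategy_sweep(ct_records, "coughing")
        bd = reports["DP"].breakdowns["sensitivity"]
        assert bd == {"without_ie": (12, 16), "with_ie": (16, 24), "combined": (28, 40)}
        assert reports["PS1"].breakdowns["sensitivity"]["with_ie"] is None
        assert reports["PS2"].breakdowns["specificity"]["without_ie"] is None


class TestApplyEstimand:
    def test_ct_spec_event_free_principal_stratum(self):
        records = ct_example_records(event_type="arrhythmical_breathing")
        report, audit = apply_estimand(records, load_ct_estimand())
        sens = report.measures["sensitivity"]
        assert (sens.numerator, sens.denominator) == (12, 16)
        assert sens.estimate == 0.75
        assert report.n_excluded == 64

    def test_no_declared_events_clean_data_is_plain_accuracy(self, ct_records):
        clean = [r for r in ct_records if not r.occurred_events]
        report, _ = apply_estimand(clean, make_spec())
        sens = report.measures["sensitivity"]
        assert (sens.numerator, sens.denominator) == (12, 16)

    def test_occurred_event_without_strategy_raises(self, ct_records):
        with pytest.raises(SpecValidationError, match="coughing"):
            apply_estimand(ct_records, make_spec())

    def test_determinism_byte_identical_reports(self, ct_records):
        spec = make_spec({"coughing": {"strategy": "diagnostic_policy"}})
        r1, a1 = apply_estimand(ct_records, spec, EngineOptions(seed=11))
        r2, a2 = apply_estimand(ct_records, spec, EngineOptions(seed=11))
        assert r1.to_json() == r2.to_json()
        assert a1.to_json() == a2.to_json()

    def test_subject_conservation(self, ct_records):
        for label_spec in (
            {"coughing": {"strategy": "diagnostic_policy"}},
            {"coughing": {"strategy": "principal_stratum", "options": {"stratum": "event_free"}}},
        ):
            report, _ = apply_estimand(ct_records, make_spec(label_spec))
            assert (
                report.n_included + report.n_excluded + report.n_inconclusive
                == len(ct_records)
            )

    def test_audit_traces_strategy_and_event(self, ct_records):
        spec = make_spec({"coughing": {"strategy": "setback"}})
        _, audit = apply_estimand(ct_records, spec)
        assert len(audit.entries) == 200
        affected = [e for e in audit.entries if e.governing_event == "coughing"]
        assert len(affected) == 64
        assert all(e.strategy == "setback" for e in affected)

    def test_unresolved_missing_decision_is_hard_error_listing_subjects(self):
        records = [
            SubjectRecord(
                subject_id="m1",
                true_condition=Condition.DISEASED,
                index_result=Result.ABSENT,
            ),
            SubjectRecord(
                subject_id="ok",
                true_condition=Condition.DISEASED,
                index_result=Result.POSITIVE,
            ),
        ]
        with pytest.raises(ImputationError, match="m1"):
            apply_estimand(records, make_spec())

    def test_event_unrelated_missingness_policies(self):
        records = [
            SubjectRecord(
                subject_id="m1",
                true_condition=Condition.DISEASED,
                index_result=Result.ABSENT,
            ),
            SubjectRecord(
                subject_id="ok",
                true_condition=Condition.DISEASED,
                index_result=Result.POSITIVE,
            ),
        ]
        report, _ = apply_estimand(
            records,
            make_spec(measures=("sensitivity",)),
            EngineOptions(missing_index="exclude_with_warning"),
        )
        assert report.measures["sensitivity"].denominator == 1
        assert any("bias" in w for w in report.warnings)

        report2, _ = apply_estimand(
            records,
            make_spec(measures=("sensitivity",)),
            EngineOptions(missing_index="constant:negative"),
        )
        assert report2.measures["sensitivity"].denominator == 2

    def test_population_filter_runs_before_events(self):
        records = [
            SubjectRecord(
                subject_id=f"s{i}",
                true_condition=Condition.DISEASED,
                index_result=Result.POSITIVE,
                covariates={"age": age},
            )
            for i, age in enumerate([25, 45, 70])
        ]
        spec = make_spec(
            measures=("sensitivity",),
            population={"description": "adults 30+", "filter_query": "age >= 30"},
        )
        report, _ = apply_estimand(records, spec)
        assert report.n_population_filtered == 1
        assert report.measures["sensitivity"].denominator == 2

    def test_derived_measures_from_spec(self, ct_records):
        spec = make_spec(
            {"coughing": {"strategy": "diagnostic_policy"}},
            measures=("sensitivity", "specificity", "youden", "ppv"),
        )
        report, _ = apply_estimand(ct_records, spec, EngineOptions(prevalence=0.2))
        assert report.derived.youden == pytest.approx(0.60)
        assert report.derived.ppv == pytest.approx(0.7 * 0.2 / (0.7 * 0.2 + 0.1 * 0.8))


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = DiagnosticAccuracyEstimator(spec=None, ci_level=0.9)
        est2 = est.set_params(ci_level=0.99)
        assert est2.get_params()["ci_level"] == 0.99

    def test_fit_accepts_dataframe(self, ct_records):
        frame = records_to_frame(ct_records)
        est = DiagnosticAccuracyEstimator(
            spec=make_spec({"coughing": {"strategy": "diagnostic_policy"}})
        ).fit(frame)
        assert est.sensitivity_ == 0.70
        assert est.specificity_ == 0.90
        assert est.score() == pytest.approx(0.60)

    def test_fit_from_spec_path(self, tmp_path, ct_records):
        from diagest.study_data import write_estimand_spec

        spec = make_spec({"coughing": {"strategy": "setback"}})
        p = tmp_path / "spec.yaml"
        write_estimand_spec(spec, p)
        est = DiagnosticAccuracyEstimator(spec=str(p)).fit(ct_records)
        assert est.sensitivity_ == 0.30


class TestResolveCondition:
    def test_conclusive_references_map_identically(self):
        records = [
            SubjectRecord(subject_id="a", reference_result=Result.POSITIVE,
                          index_result=Result.POSITIVE),
            SubjectRecord(subject_id="b", reference_result=Result.NEGATIVE,
                          index_result=Result.NEGATIVE),
        ]
        out = resolve_condition(records, "reference")
        assert out[0].true_condition is Condition.DISEASED
        assert out[1].true_condition is Condition.NON_DISEASED

    def test_exclude_with_warning_reduces_denominator_exactly(self, ct_records):
        from dataclasses import replace

        records = [
            replace(r, reference_result=Result.ABSENT, true_condition=Condition.UNKNOWN)
            if i < 10
            else replace(
                r,
                reference_result=(
                    Result.POSITIVE
                    if r.true_condition is Condition.DISEASED
                    else Result.NEGATIVE
                ),
            )
            for i, r in enumerate(ct_records)
        ]
        spec = make_spec(
            {"coughing": {"strategy": "diagnostic_policy"}},
            condition_source="reference",
        )
        report, audit = apply_estimand(records, spec)
        assert report.n_excluded == 10
        n_sens = report.measures["sensitivity"].denominator
        n_spec = report.measures["specificity"].denominator
        assert n_sens + n_spec == 190
        assert any("reference" in w for w in report.warnings)
        assert any("reference standard" in lim for lim in report.limitations)

    def test_bernoulli_imputation_recovers_prevalence(self):
        n = 10_000
        records = [
            SubjectRecord(
                subject_id=f"s{i}",
                reference_result=Result.ABSENT,
                index_result=Result.NEGATIVE,
            )
            for i in range(n)
        ]
        out = resolve_condition(
            records,
            "reference",
            EngineOptions(reference_missing="impute_bernoulli", prevalence=0.2, seed=123),
        )
        p_hat = sum(r.true_condition is Condition.DISEASED for r in out) / n
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(p_hat - 0.2) < 3 * se


class TestValidateImputationPlan:
    def test_no_imputers_gives_empty_list(self):
        assert validate_imputation_plan(make_spec()) == []

    def test_imputing_into_event_free_principal_stratum_is_error(self):
        spec = make_spec(
            {"ie": {"strategy": "principal_stratum", "options": {"stratum": "event_free"}}}
        )
        options = EngineOptions(
            imputation_plan=(
                ImputationDirective(target="index", imputer="constant:negative",
                                    scope="event_affected", event_type="ie"),
            )
        )
        issues = validate_imputation_plan(spec, options)
        assert any(i.level == "error" and "stratum" in i.message for i in issues)

    def test_imputing_index_for_healthy_with_sensitivity_is_error(self):
        spec = make_spec(measures=("sensitivity",))
        options = EngineOptions(
            imputation_plan=(
                ImputationDirective(target="index", imputer="constant:negative",
                                    scope="non_diseased"),
            )
        )
        issues = validate_imputation_plan(spec, options)
        assert any("sensitivity" in i.message for i in issues)

    def test_imputing_reference_for_index_positives_with_ppv_is_error(self):
        spec = make_spec(measures=("sensitivity", "specificity", "ppv"))
        options = EngineOptions(
            imputation_plan=(
                ImputationDirective(target="reference", imputer="bernoulli:0.2",
                                    scope="index_positive"),
            )
        )
        issues = validate_imputation_plan(spec, options)
        assert any("partial-verification" in i.message for i in issues)

    def test_engine_refuses_to_fit_with_forbidden_plan(self, ct_records):
        spec = make_spec(
            {"coughing": {"strategy": "principal_stratum",
                          "options": {"stratum": "event_free"}}}
        )
        est = DiagnosticAccuracyEstimator(
            spec=spec,
            imputation_plan=(
                ImputationDirective(target="index", imputer="constant:negative",
                                    scope="all"),
            ),
        )
        with pytest.raises(SpecValidationError, match="imputation plan"):
            est.fit(ct_records)
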