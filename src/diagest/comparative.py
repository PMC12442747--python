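"""Comparative accuracy estimands: two tests, contrasts, paired strata.

In a paired design every subject undergoes both tests, so interfering-event
occurrence is observed for each test and a shared event type handled with
the principal-stratum strategy partitions subjects into four strata (event
in both tests, in neither, only in the index test, only in the comparator).
In an unpaired design each subject receives one test; stratum membership
for the unassigned test is unobservable and would have to be predicted —
that prediction model is an explicit, unimplemented extension point.

Accuracy contrasts (difference, ratio, odds ratio) are computed for
sensitivity and specificity. Interval estimation is by seeded bootstrap:
nonparametric over subjects for paired data, parametric over the two
independent binomial strata when only the two per-test reports are
available (the unpaired case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np

from .engine import DiagnosticAccuracyEstimator, EngineOptions
from .errors import UnpairedDesignError
from .measures import AccuracyReport
from .study_data import (
    Condition,
    Decision,
    EstimandSpec,
    EventOccurrence,
    Result,
    SubjectRecord,
)

__all__ = [
    "TestArm",
    "ComparativeRecord",
    "ContrastEstimate",
    "ComparativeReport",
    "contrast_value",
    "compare_accuracy",
    "paired_principal_strata",
    "predict_stratum_membership",
]

Contrast = Literal["difference", "ratio", "odds"]


@dataclass(frozen=True)
class TestArm:
    """Per-test fields of a comparative record."""

    index_result: Result = Result.ABSENT
    events: tuple[EventOccurrence, ...] = ()
    partial_result: Result = Result.ABSENT
    counterfactual_result: Result = Result.ABSENT

    def has_event(self, event_type: str) -> bool:
        return any(e.occurred and e.event_type == event_type for e in self.events)


@dataclass(frozen=True)
class ComparativeRecord:
    """One participant in a two-test comparative study."""

    subject_id: str
    true_condition: Condition = Condition.UNKNOWN
    reference_result: Result = Result.ABSENT
    design: Literal["paired", "unpaired"] = "paired"
    index: Optional[TestArm] = None
    comparator: Optional[TestArm] = None
    assignment: Optional[Literal["index", "comparator"]] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design == "paired":
            if self.index is None or self.comparator is None:
                raise UnpairedDesignError(
                    f"subject {self.subject_id}: a paired record needs both tests' fields"
                )
        else:
            present = [a for a in (self.index, self.comparator) if a is not None]
            if len(present) != 1 or self.assignment is None:
                raise UnpairedDesignError(
                    f"subject {self.subject_id}: an unpaired record needs exactly "
                    "one test's fields and an assignment"
                )

    def arm_record(self, arm: Literal["index", "comparator"]) -> SubjectRecord:
        """Project one test's fields onto a single-test subject record."""
        a = getattr(self, arm)
        if a is None:
            raise UnpairedDesignError(
                f"subject {self.subject_id} was not assigned to the {arm} test"
            )
        return SubjectRecord(
            subject_id=self.subject_id,
            true_condition=self.true_condition,
            reference_result=self.reference_result,
            index_result=a.index_result,
            events=a.events,
            partial_result=a.partial_result,
            counterfactual_result=a.counterfactual_result,
            covariates=self.covariates,
        )


@dataclass(frozen=True)
class ContrastEstimate:
    """A contrast of one accuracy measure between two tests."""

    measure: str
    contrast: Contrast
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    infinite: bool = False


@dataclass
class ComparativeReport:
    contrast: Contrast
    sensitivity: ContrastEstimate
    specificity: ContrastEstimate
    report_index: Optional[AccuracyReport] = None
    report_comparator: Optional[AccuracyReport] = None
    n_boot: int = 0
    ci_level: float = 0.95
    seed: Optional[int] = None


def contrast_value(a: float, b: float, contrast: Contrast) -> tuple[float, bool]:
    """Contrast of two proportions; returns (value, infinite_flag)."""
    if contrast == "difference":
        return a - b, False
    if contrast == "ratio":
        if b == 0.0:
            return (math.inf if a > 0 else math.nan), True
        return a / b, False
    if contrast == "odds":
        if a == b:  # identical accuracies have odds ratio 1 even at the boundary
            return 1.0, False
        odds_a = math.inf if a == 1.0 else a / (1.0 - a)
        odds_b = math.inf if b == 1.0 else b / (1.0 - b)
        if odds_b == 0.0 or math.isinf(odds_a):
            return math.inf, True
        if math.isinf(odds_b):
            return 0.0, True
        return odds_a / odds_b, False
    raise ValueError(f"unknown contrast '{contrast}'")


def _bootstrap_ci(
    samples: np.ndarray, ci_level: float
) -> tuple[Optional[float], Optional[float]]:
    finite = samples[np.isfinite(samples)]
    if finite.size == 0:
        return None, None
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _decision_arrays(
    records: Sequence[ComparativeRecord],
    spec_index: EstimandSpec,
    spec_comparator: EstimandSpec,
    options: EngineOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, AccuracyReport, AccuracyReport]:
    """Run the engine once per test; return per-subject coded decisions.

    Codes: 1 positive, 0 negative, -1 held out (excluded/inconclusive).
    The bootstrap then resamples subjects, not engine runs, so stochastic
    imputations are fixed at their seeded values.
    """
    reports = {}
    coded = {}
    conditions = None
    for arm, spec in (("index", spec_index), ("comparator", spec_comparator)):
        arm_records = [r.arm_record(arm) for r in records]
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
        ).fit(arm_records)
        reports[arm] = est.report_
        code = np.full(len(records), -1, dtype=np.int8)
        for i, e in enumerate(est.audit_.entries):
            if e.decision is Decision.POSITIVE:
                code[i] = 1
            elif e.decision is Decision.NEGATIVE:
                code[i] = 0
        coded[arm] = code
        if conditions is None:
            conditions = np.array(
                [e.condition is Condition.DISEASED for e in est.audit_.entries]
            )
    return (
        coded["index"],
        coded["comparator"],
        conditions,
        reports["index"],
        reports["comparator"],
    )


def _proportion_from_codes(
    codes: np.ndarray, diseased: np.ndarray, target_diseased: bool, correct_code: int
) -> float:
    mask = (diseased == target_diseased) & (codes >= 0)
    n = int(mask.sum())
    return math.nan if n == 0 else float((codes[mask] == correct_code).sum() / n)


def compare_accuracy(
    report_index: Optional[AccuracyReport] = None,
    report_comparator: Optional[AccuracyReport] = None,
    contrast: Contrast = "difference",
    *,
    records: Optional[Sequence[ComparativeRecord]] = None,
    spec_index: Optional[EstimandSpec] = None,
    spec_comparator: Optional[EstimandSpec] = None,
    options: Optional[EngineOptions] = None,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: Optional[int] = None,
) -> ComparativeReport:
    """Contrast the accuracy of two tests, with a seeded bootstrap CI.

    Two call shapes:

    * two finished :class:`AccuracyReport` objects — the CI resamples the
      two binomial strata independently (appropriate for unpaired designs);
    * paired subject-level ``records`` plus one estimand spec per test
      (possibly with different strategies, as comparative estimands often
      require) — the CI is a nonparametric bootstrap over subjects, which
      respects the within-subject pairing.
    """
    rng = np.random.default_rng(seed)

    if records is not None:
        if spec_index is None or spec_comparator is None:
            raise ValueError("paired comparison needs spec_index and spec_comparator")
        if any(r.design != "paired" for r in records):
            raise UnpairedDesignError(
                "subject-level bootstrap requires a paired design; for unpaired "
                "designs compare the two per-arm reports instead"
            )
        options = options or EngineOptions()
        code_a, code_b, diseased, rep_a, rep_b = _decision_arrays(
            records, spec_index, spec_comparator, options
        )
        n = len(records)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = {"sensitivity": [], "specificity": []}
        for row in idx:
            da, db, dis = code_a[row], code_b[row], diseased[row]
            for m, target, correct in (
                ("sensitivity", True, 1),
                ("specificity", False, 0),
            ):
                pa = _proportion_from_codes(da, dis, target, correct)
                pb = _proportion_from_codes(db, dis, target, correct)
                if math.isnan(pa) or math.isnan(pb):
                    boots[m].append(math.nan)
                else:
                    boots[m].append(contrast_value(pa, pb, contrast)[0])
    else:
        if report_index is None or report_comparator is None:
            raise ValueError(
                "compare_accuracy needs either two reports or paired records + specs"
            )
        rep_a, rep_b = report_index, report_comparator
        boots = {"sensitivity": [], "specificity": []}
        for m in ("sensitivity", "specificity"):
            ka, na = rep_a.measures[m].numerator, rep_a.measures[m].denominator
            kb, nb = rep_b.measures[m].numerator, rep_b.measures[m].denominator
            pa_star = rng.binomial(na, ka / na, size=n_boot) / na
            pb_star = rng.binomial(nb, kb / nb, size=n_boot) / nb
            boots[m] = [
                contrast_value(float(x), float(y), contrast)[0]
                for x, y in zip(pa_star, pb_star)
            ]

    estimates = {}
    for m in ("sensitivity", "specificity"):
        pa = rep_a.measures[m].estimate
        pb = rep_b.measures[m].estimate
        value, infinite = contrast_value(pa, pb, contrast)
        lo, hi = _bootstrap_ci(np.asarray(boots[m], dtype=float), ci_level)
        estimates[m] = ContrastEstimate(m, contrast, value, lo, hi, infinite)

    return ComparativeReport(
        contrast=contrast,
        sensitivity=estimates["sensitivity"],
        specificity=estimates["specificity"],
        report_index=rep_a,
        report_comparator=rep_b,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# paired principal strata
# ---------------------------------------------------------------------------

STRATUM_NAMES = ("both", "neither", "index_only", "comparator_only")


@dataclass
class PairedStrata:
    """Partition of a paired study by per-test event occurrence."""

    event_type: str
    counts: dict[str, int]
    subject_ids: dict[str, list[str]]
    #: stratum -> test -> (sens_fraction, spec_fraction) or None when empty
    accuracy: dict[str, dict[str, dict[str, Optional[tuple[int, int]]]]]


def paired_principal_strata(
    records: Sequence[ComparativeRecord], event_type: str
) -> PairedStrata:
    """Partition paired subjects into the four potential event strata.

    Unpaired records raise: their stratum membership for the test they did
    not receive is unknown and would need :func:`predict_stratum_membership`.
    """
    for r in records:
        if r.design != "paired":
            raise UnpairedDesignError(
                f"subject {r.subject_id}: stratum membership for the unassigned "
                "test is unobserved in an unpaired design and must be predicted "
                "(see predict_stratum_membership)"
            )

    ids: dict[str, list[str]] = {s: [] for s in STRATUM_NAMES}
    members: dict[str, list[ComparativeRecord]] = {s: [] for s in STRATUM_NAMES}
    for r in records:
        in_index = r.index.has_event(event_type)  # type: ignore[union-attr]
        in_comp = r.comparator.has_event(event_type)  # type: ignore[union-attr]
        stratum = {
            (True, True): "both",
            (False, False): "neither",
            (True, False): "index_only",
            (False, True): "comparator_only",
        }[(in_index, in_comp)]
        ids[stratum].append(r.subject_id)
        members[stratum].append(r)

    def frac(recs: list[ComparativeRecord], arm: str, target: Condition):
        num = den = 0
        correct = Result.POSITIVE if target is Condition.DISEASED else Result.NEGATIVE
        for r in recs:
            if r.true_condition is not target:
                continue
            res = getattr(r, arm).index_result
            if res in (Result.POSITIVE, Result.NEGATIVE):
                den += 1
                if res is correct:
                    num += 1
        return None if den == 0 else (num, den)

    accuracy = {
        s: {
            arm: {
                "sensitivity": frac(members[s], arm, Condition.DISEASED),
                "specificity": frac(members[s], arm, Condition.NON_DISEASED),
            }
            for arm in ("index", "comparator")
        }
        for s in STRATUM_NAMES
    }
    return PairedStrata(
        event_type=event_type,
        counts={s: len(ids[s]) for s in STRATUM_NAMES},
        subject_ids=ids,
        accuracy=accuracy,
    )


def predict_stratum_membership(records, event_type, model=None):
    """Extension point for unpaired designs (not implemented).

    Predicting a subject's potential event occurrence under the test they
    were not assigned to requires a membership model (e.g. from covariates);
    no canonical model is defined here.
    """
    raise NotImplementedError(
        "stratum-membership prediction for unpaired designs is an extension "
        "point: supply and fit your own membership model; this package does "
        "not define one"
    )
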