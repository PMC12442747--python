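"""The worked CT-scan example study that ships with the package.

A notional study of computed tomography for detecting lung carcinoma in 200
subjects: 40 with the target condition, 160 without. One interfering event
(coughing during the scan, leading to a possibly blurred image) occurred in
24 diseased and 40 healthy subjects. Observed results:

=====================  ==========  =======
                       without IE  with IE
=====================  ==========  =======
diseased, positive     12          16
diseased, negative     4           8
healthy,  positive     10          6
healthy,  negative     110         34
=====================  ==========  =======

The records also carry the per-subject information the hypothetical and
while-under-monitoring strategies need, encoding the example's assumptions:

* counterfactual results (had the event not occurred) with 18/24 diseased
  and 37/40 healthy with-IE subjects correct — the event degrades accuracy,
  and absent the event the with-IE subjects resemble the rest;
* pre-event partial results with 12/24 and 28/40 correct — only part of the
  scan is available before the event, so partial accuracy is lower.

Note one arithmetic point about the hypothetical row: its specificity is
147/160 = 91.88%. A figure of 92.88% sometimes quoted for this example is
inconsistent with the example's own cell counts and is treated here as a
transcription error.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .study_data import (
    Condition,
    EstimandSpec,
    EventOccurrence,
    Result,
    StratifiedCounts,
    StratumCell,
    SubjectRecord,
    read_estimand_spec,
)

__all__ = [
    "ct_example_counts",
    "ct_example_records",
    "ct_estimand_path",
    "load_ct_estimand",
]


def ct_example_counts(event_type: str = "coughing") -> StratifiedCounts:
    """The example's stratified count table."""
    return StratifiedCounts(
        diseased_without_ie=StratumCell(positive=12, negative=4),
        diseased_with_ie=StratumCell(positive=16, negative=8),
        healthy_without_ie=StratumCell(positive=10, negative=110),
        healthy_with_ie=StratumCell(positive=6, negative=34),
        event_type=event_type,
    )


def _block(
    records: list[SubjectRecord],
    condition: Condition,
    with_ie: bool,
    n: int,
    n_observed_positive: int,
    event_type: str,
    n_counterfactual_positive: int | None = None,
    n_partial_positive: int | None = None,
) -> None:
    """Append ``n`` records; the first k of each field are positive.

    Any joint assignment with the right marginals gives the same accuracy
    under every strategy, since each strategy reads one field at a time.
    """
    ref = Result.POSITIVE if condition is Condition.DISEASED else Result.NEGATIVE
    for i in range(n):
        observed = Result.POSITIVE if i < n_observed_positive else Result.NEGATIVE
        if with_ie:
            events = (EventOccurrence(event_type, occurred=True),)
            cf = (
                Result.POSITIVE
                if i < (n_counterfactual_positive or 0)
                else Result.NEGATIVE
            )
            partial = (
                Result.POSITIVE if i < (n_partial_positive or 0) else Result.NEGATIVE
            )
        else:
            events = ()
            cf = observed
            partial = Result.ABSENT
        records.append(
            SubjectRecord(
                subject_id=f"ct{len(records) + 1:03d}",
                true_condition=condition,
                reference_result=ref,
                index_result=observed,
                events=events,
                partial_result=partial,
                counterfactual_result=cf,
            )
        )


def ct_example_records(event_type: str = "coughing") -> list[SubjectRecord]:
    """The 200 example subjects as fully populated records."""
    records: list[SubjectRecord] = []
    _block(records, Condition.DISEASED, False, 16, 12, event_type)
    _block(
        records,
        Condition.DISEASED,
        True,
        24,
        16,
        event_type,
        n_counterfactual_positive=18,  # 18/24 correct had the event not occurred
        n_partial_positive=12,  # 12/24 correct from the pre-event scan part
    )
    _block(records, Condition.NON_DISEASED, False, 120, 10, event_type)
    _block(
        records,
        Condition.NON_DISEASED,
        True,
        40,
        6,
        event_type,
        n_counterfactual_positive=3,  # 37/40 correct (negative) counterfactually
        n_partial_positive=12,  # 28/40 correct from the pre-event scan part
    )
    assert len(records) == 200
    return records


def ct_estimand_path() -> Path:
    """Path to the packaged CT-example estimand specification (YAML)."""
    return Path(resources.files("diagest").joinpath("data", "ct_estimand.yaml"))


def load_ct_estimand() -> EstimandSpec:
    """The example estimand: principal stratum for arrhythmical breathing,
    indicative-positive for early termination, hypothetical for
    claustrophobic seizure."""
    return read_estimand_spec(ct_estimand_path())
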