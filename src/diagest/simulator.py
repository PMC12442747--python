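"""Synthetic diagnostic accuracy studies with disease-state-dependent IEs.

The generative model reflects how interfering events behave in diagnostic
studies: their occurrence is tied to the subject's true disease state (a
diseased patient may, for example, terminate the test more often), and their
occurrence degrades the test's accuracy. Per subject:

1. condition ~ Bernoulli(prevalence);
2. the *counterfactual* result — the result had no event occurred — is drawn
   from (sens0, spec0) given the condition;
3. an event occurs with the state-specific rate (``ie_rate_diseased`` or
   ``ie_rate_healthy``);
4. if it occurred, the observed result is redrawn from the degraded
   accuracies (sens_ie, spec_ie); with probability ``p_absent_given_ie`` the
   event instead leaves no test decision at all (an absent result); a
   pre-event partial result is drawn from (partial_sens, partial_spec);
5. if it did not occur, the observed result equals the counterfactual.

Counterfactual results are always stored (they are free to generate), so the
hypothetical strategy's oracle imputer and principal-stratum checks have an
exact target; code paths for real data never read them.

Default parameters are the conditions of the worked CT-scan example that
ships with the package: 200 subjects, prevalence 0.2, baseline sensitivity
0.75 and specificity 110/120, event rates 0.6 (diseased) and 0.25 (healthy),
degraded accuracies 2/3 and 0.85, partial-result accuracies 0.5 and 0.7, and
no event-caused absences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import EngineOptions, strategy_sweep
from .errors import SpecValidationError
from .study_data import (
    Condition,
    EventOccurrence,
    Result,
    SubjectRecord,
)

__all__ = [
    "SimulationParams",
    "simulate_study",
    "analytic_targets",
    "strategy_recovery_experiment",
    "simulate_paired_study",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study generator (all probabilities)."""

    n: int = 200
    prevalence: float = 0.2
    sens0: float = 0.75  #: sensitivity absent any IE
    spec0: float = 110 / 120  #: specificity absent any IE
    ie_rate_diseased: float = 0.6
    ie_rate_healthy: float = 0.25
    sens_ie: float = 2 / 3  #: sensitivity when the IE occurred
    spec_ie: float = 0.85  #: specificity when the IE occurred
    p_absent_given_ie: float = 0.0  #: IE leaves no test decision
    partial_sens: float = 0.5  #: accuracy of the pre-IE partial result
    partial_spec: float = 0.7
    event_type: str = "coughing"
    #: additional independent event types (rate per subject) with uniform
    #: timestamps, solely to exercise multi-event resolution
    extra_event_rates: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecValidationError("n must be >= 1")
        probs = {
            "prevalence": self.prevalence,
            "sens0": self.sens0,
            "spec0": self.spec0,
            "ie_rate_diseased": self.ie_rate_diseased,
            "ie_rate_healthy": self.ie_rate_healthy,
            "sens_ie": self.sens_ie,
            "spec_ie": self.spec_ie,
            "p_absent_given_ie": self.p_absent_given_ie,
            "partial_sens": self.partial_sens,
            "partial_spec": self.partial_spec,
            **{f"extra_event_rates[{k}]": v for k, v in self.extra_event_rates.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise SpecValidationError(f"{name} must be in [0, 1], got {p}")


def _draw_results(
    rng: np.random.Generator, diseased: np.ndarray, sens: float, spec: float
) -> np.ndarray:
    """Vector of correct-decision indicators -> positive/negative results."""
    u = rng.random(diseased.shape[0])
    p_positive = np.where(diseased, sens, 1.0 - spec)
    return u < p_positive  # True = positive result


def simulate_study(params: SimulationParams) -> list[SubjectRecord]:
    """Generate one synthetic study; fully reproducible given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n

    diseased = rng.random(n) < params.prevalence
    counterfactual_pos = _draw_results(rng, diseased, params.sens0, params.spec0)
    ie_rate = np.where(diseased, params.ie_rate_diseased, params.ie_rate_healthy)
    has_ie = rng.random(n) < ie_rate
    affected_pos = _draw_results(rng, diseased, params.sens_ie, params.spec_ie)
    absent = has_ie & (rng.random(n) < params.p_absent_given_ie)
    partial_pos = _draw_results(rng, diseased, params.partial_sens, params.partial_spec)
    times = rng.random(n)
    extra = {
        etype: (rng.random(n) < rate, rng.random(n))
        for etype, rate in params.extra_event_rates.items()
    }

    def result(pos: bool) -> Result:
        return Result.POSITIVE if pos else Result.NEGATIVE

    records: list[SubjectRecord] = []
    for i in range(n):
        cond = Condition.DISEASED if diseased[i] else Condition.NON_DISEASED
        cf = result(counterfactual_pos[i])
        events: list[EventOccurrence] = []
        if has_ie[i]:
            events.append(
                EventOccurrence(params.event_type, occurred=True, time=float(times[i]))
            )
            observed = Result.ABSENT if absent[i] else result(affected_pos[i])
            partial = result(partial_pos[i])
        else:
            observed = cf
            partial = Result.ABSENT
        for etype, (flags, etimes) in extra.items():
            if flags[i]:
                events.append(
                    EventOccurrence(etype, occurred=True, time=float(etimes[i]))
                )
        records.append(
            SubjectRecord(
                subject_id=f"sim{i + 1:05d}",
                true_condition=cond,
                reference_result=(
                    Result.POSITIVE if diseased[i] else Result.NEGATIVE
                ),
                index_result=observed,
                events=tuple(events),
                partial_result=partial,
                counterfactual_result=cf,
            )
        )
    return records


def analytic_targets(params: SimulationParams) -> dict[str, tuple[float, float]]:
    """Closed-form (sensitivity, specificity) targets per strategy label.

    Derived from the generative model with no event-caused absences:
    diagnostic policy mixes baseline and degraded accuracy by the event
    rate; the oracle hypothetical recovers the baseline; setback zeroes the
    with-event contribution; the indicative rules add or remove the whole
    with-event stratum; the principal strata isolate the two components.
    """
    rd, rh = params.ie_rate_diseased, params.ie_rate_healthy
    s0, p0 = params.sens0, params.spec0
    s1, p1 = params.sens_ie, params.spec_ie
    return {
        "DP": ((1 - rd) * s0 + rd * s1, (1 - rh) * p0 + rh * p1),
        "HY": (s0, p0),
        "WUM": (
            (1 - rd) * s0 + rd * params.partial_sens,
            (1 - rh) * p0 + rh * params.partial_spec,
        ),
        "PS1": (s0, p0),
        "PS2": (s1, p1),
        "IE+": ((1 - rd) * s0 + rd, (1 - rh) * p0),
        "IE-": ((1 - rd) * s0, (1 - rh) * p0 + rh),
        "SB": ((1 - rd) * s0, (1 - rh) * p0),
    }


def strategy_recovery_experiment(
    params: SimulationParams,
    labels: Sequence[str] = ("DP", "HY", "PS1", "PS2", "IE+", "IE-", "SB", "WUM"),
    replicates: int = 20,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Monte-Carlo check that each strategy estimates its analytic target.

    Simulates ``replicates`` studies, analyses each under the requested
    strategy configurations, and summarises per strategy and measure: the
    mean estimate, the closed-form target, bias, RMSE, and the Monte-Carlo
    standard error of the mean.
    """
    if replicates < 1:
        raise SpecValidationError("replicates must be >= 1")
    targets = analytic_targets(params)
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    estimates: dict[tuple[str, str], list[float]] = {
        (label, m): [] for label in labels for m in ("sensitivity", "specificity")
    }
    for r in range(replicates):
        rep_params = SimulationParams(
            **{**params.__dict__, "seed": int(seeds[r])}
        )
        records = simulate_study(rep_params)
        reports = strategy_sweep(
            records, params.event_type, EngineOptions(seed=int(seeds[r])), labels
        )
        for label, report in reports.items():
            for m in ("sensitivity", "specificity"):
                estimates[(label, m)].append(report.measures[m].estimate)

    rows = []
    for label in labels:
        for j, m in enumerate(("sensitivity", "specificity")):
            vals = np.asarray(estimates[(label, m)])
            target = targets[label][j]
            rows.append(
                {
                    "strategy": label,
                    "measure": m,
                    "mean_estimate": vals.mean(),
                    "target": target,
                    "bias": vals.mean() - target,
                    "rmse": float(np.sqrt(np.mean((vals - target) ** 2))),
                    "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1
                    else float("nan"),
                    "replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def simulate_paired_study(
    n: int = 400,
    prevalence: float = 0.3,
    sens_index: float = 0.85,
    spec_index: float = 0.9,
    sens_comparator: float = 0.7,
    spec_comparator: float = 0.85,
    ie_rate_index: float = 0.0,
    ie_rate_comparator: float = 0.0,
    event_type: str = "termination",
    seed: Optional[int] = None,
):
    """Generate a paired two-test study (both tests on every subject).

    Test results are conditionally independent given the condition; event
    occurrences are independent per test with the given rates, so the four
    potential strata have multinomial proportions (p1*p2, (1-p1)*(1-p2),
    p1*(1-p2), (1-p1)*p2).
    """
    from .comparative import ComparativeRecord, TestArm

    rng = np.random.default_rng(seed)
    diseased = rng.random(n) < prevalence

    def arm(sens: float, spec: float, ie_rate: float) -> list[TestArm]:
        pos = _draw_results(rng, diseased, sens, spec)
        has_ie = rng.random(n) < ie_rate
        arms = []
        for i in range(n):
            events = (
                (EventOccurrence(event_type, occurred=True, time=0.0),)
                if has_ie[i]
                else ()
            )
            arms.append(
                TestArm(
                    index_result=(
                        Result.POSITIVE if pos[i] else Result.NEGATIVE
                    ),
                    events=events,
                )
            )
        return arms

    arms_a = arm(sens_index, spec_index, ie_rate_index)
    arms_b = arm(sens_comparator, spec_comparator, ie_rate_comparator)
    return [
        ComparativeRecord(
            subject_id=f"pair{i + 1:05d}",
            true_condition=(
                Condition.DISEASED if diseased[i] else Condition.NON_DISEASED
            ),
            reference_result=(
                Result.POSITIVE if diseased[i] else Result.NEGATIVE
            ),
            design="paired",
            index=arms_a[i],
            comparator=arms_b[i],
        )
        for i in range(n)
    ]
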