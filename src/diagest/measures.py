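"""Accuracy measures with confidence intervals, and the report container.

Sensitivity is the probability that a diseased subject is correctly
identified; specificity the probability that a healthy subject is. Both are
binomial proportions; intervals default to the Wilson score method, which
behaves well at boundary proportions, with the exact Clopper-Pearson
interval available by option.

Inconclusive decisions default to a separately reported category. They can
instead be counted as positive, counted as negative, or excluded — the last
with a warning, because excluding inconclusive subjects restricts the
analysed spectrum and can bias the estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

from statsmodels.stats.proportion import proportion_confint

from .errors import ImputationError, UndefinedEstimateError
from .study_data import Condition, Decision, DerivedDecision

__all__ = [
    "ProportionEstimate",
    "DerivedMeasures",
    "AccuracyReport",
    "proportion_with_ci",
    "sensitivity",
    "specificity",
    "derived_measures",
    "format_percent",
]

CIMethod = Literal["wilson", "clopper_pearson"]
InconclusivePolicy = Literal["separate", "positive", "negative", "exclude"]

_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}

#: warning attached when inconclusive results are dropped rather than reported
EXCLUSION_BIAS_WARNING = (
    "inconclusive results were excluded from the denominator; excluding such "
    "subjects restricts the analysed spectrum and could introduce bias in the "
    "accuracy estimates"
)


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with a two-sided confidence interval."""

    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    ci_method: str = "wilson"
    n_excluded: int = 0
    n_inconclusive: int = 0

    def __str__(self) -> str:
        return (
            f"{self.numerator}/{self.denominator} = {format_percent(self.estimate)} "
            f"({self.ci_level:.0%} CI {format_percent(self.ci_low)}"
            f"-{format_percent(self.ci_high)})"
        )


def format_percent(x: float, decimals: int = 2) -> str:
    """Percent formatting used in report tables: up to two decimals, no
    trailing zeros (``0.9`` -> ``90%``, ``0.9188`` -> ``91.88%``)."""
    s = f"{100 * x:.{decimals}f}".rstrip("0").rstrip(".")
    return f"{s}%"


def proportion_with_ci(
    numerator: int,
    denominator: int,
    ci_level: float = 0.95,
    ci_method: CIMethod = "wilson",
    **extra: int,
) -> ProportionEstimate:
    """Point estimate and CI for ``numerator / denominator``."""
    if denominator <= 0:
        raise UndefinedEstimateError(
            "empty denominator: the requested accuracy measure is undefined "
            "(no eligible subjects)"
        )
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    low, high = proportion_confint(
        numerator, denominator, alpha=1 - ci_level, method=_CI_METHODS[ci_method]
    )
    return ProportionEstimate(
        numerator=numerator,
        denominator=denominator,
        estimate=numerator / denominator,
        ci_low=max(0.0, float(low)),
        ci_high=min(1.0, float(high)),
        ci_level=ci_level,
        ci_method=ci_method,
        **extra,
    )


Joined = Iterable[tuple[DerivedDecision, Condition]]


def _proportion_measure(
    joined: Joined,
    target: Condition,
    correct_decision: Decision,
    ci_level: float,
    ci_method: CIMethod,
    inconclusive: InconclusivePolicy,
) -> ProportionEstimate:
    numerator = denominator = n_excluded = n_inconclusive = 0
    for decision, condition in joined:
        if decision.decision is Decision.NEEDS_IMPUTATION:
            raise ImputationError(
                f"subject {decision.subject_id} still needs imputation; resolve "
                "missing decisions before computing measures"
            )
        if condition is not target:
            continue
        d = decision.decision
        if d is Decision.EXCLUDED:
            n_excluded += 1
            continue
        if d is Decision.INCONCLUSIVE:
            if inconclusive in ("separate", "exclude"):
                n_inconclusive += 1
                continue
            d = Decision(inconclusive)
        denominator += 1
        if d is correct_decision:
            numerator += 1
    return proportion_with_ci(
        numerator,
        denominator,
        ci_level,
        ci_method,
        n_excluded=n_excluded,
        n_inconclusive=n_inconclusive,
    )


def sensitivity(
    joined: Joined,
    ci_level: float = 0.95,
    ci_method: CIMethod = "wilson",
    inconclusive: InconclusivePolicy = "separate",
) -> ProportionEstimate:
    """Positive decisions among non-excluded diseased subjects."""
    return _proportion_measure(
        joined, Condition.DISEASED, Decision.POSITIVE, ci_level, ci_method, inconclusive
    )


def specificity(
    joined: Joined,
    ci_level: float = 0.95,
    ci_method: CIMethod = "wilson",
    inconclusive: InconclusivePolicy = "separate",
) -> ProportionEstimate:
    """Negative decisions among non-excluded non-diseased subjects."""
    return _proportion_measure(
        joined,
        Condition.NON_DISEASED,
        Decision.NEGATIVE,
        ci_level,
        ci_method,
        inconclusive,
    )


@dataclass(frozen=True)
class DerivedMeasures:
    """Measures derived from sensitivity, specificity, and prevalence."""

    youden: float
    lr_positive: float
    lr_negative: float
    ppv: Optional[float] = None
    npv: Optional[float] = None
    prevalence: Optional[float] = None
    flags: tuple[str, ...] = ()


def derived_measures(
    sens: Union[float, ProportionEstimate],
    spec: Union[float, ProportionEstimate],
    prevalence: Optional[float] = None,
) -> DerivedMeasures:
    """Youden index, likelihood ratios, and (given a prevalence) predictive
    values, from point estimates of sensitivity and specificity.

    Zero-cell likelihood ratios are reported as infinity with a flag rather
    than raising; no continuity correction is applied.
    """
    se = sens.estimate if isinstance(sens, ProportionEstimate) else float(sens)
    sp = spec.estimate if isinstance(spec, ProportionEstimate) else float(spec)
    for name, v in (("sensitivity", se), ("specificity", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    flags: list[str] = []
    if sp == 1.0:
        lr_pos = math.inf
        flags.append("lr_positive infinite: specificity is 1 (no false positives)")
    else:
        lr_pos = se / (1.0 - sp)
    if sp == 0.0:
        lr_neg = math.inf
        flags.append("lr_negative infinite: specificity is 0")
    else:
        lr_neg = (1.0 - se) / sp

    ppv = npv = None
    if prevalence is not None:
        if not 0.0 < prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
        p = prevalence
        pos_mass = se * p + (1.0 - sp) * (1.0 - p)
        neg_mass = (1.0 - se) * p + sp * (1.0 - p)
        if pos_mass == 0.0:
            ppv = math.nan
            flags.append("ppv undefined: no positive decisions at this prevalence")
        else:
            ppv = se * p / pos_mass
        if neg_mass == 0.0:
            npv = math.nan
            flags.append("npv undefined: no negative decisions at this prevalence")
        else:
            npv = sp * (1.0 - p) / neg_mass

    return DerivedMeasures(
        youden=se + sp - 1.0,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

Fraction = tuple[int, int]  # (correct or positive count, total)


@dataclass
class AccuracyReport:
    """Estimates, intervals, per-stratum breakdowns, and bookkeeping counts."""

    measures: dict[str, ProportionEstimate]
    derived: Optional[DerivedMeasures] = None
    #: measure -> {"without_ie": (k, n) | None, "with_ie": ..., "combined": ...}
    breakdowns: dict[str, dict[str, Optional[Fraction]]] = field(default_factory=dict)
    n_input: int = 0
    n_included: int = 0
    n_excluded: int = 0
    n_inconclusive: int = 0
    n_population_filtered: int = 0
    ci_level: float = 0.95
    ci_method: str = "wilson"
    strategy_labels: dict[str, str] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()
    limitations: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        def frac(f: Optional[Fraction]) -> Optional[list[int]]:
            return None if f is None else [int(f[0]), int(f[1])]

        out: dict = {
            "measures": {
                name: {
                    "numerator": m.numerator,
                    "denominator": m.denominator,
                    "estimate": m.estimate,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "ci_level": m.ci_level,
                    "ci_method": m.ci_method,
                }
                for name, m in self.measures.items()
            },
            "breakdowns": {
                name: {k: frac(v) for k, v in bd.items()}
                for name, bd in self.breakdowns.items()
            },
            "counts": {
                "input": self.n_input,
                "included": self.n_included,
                "excluded": self.n_excluded,
                "inconclusive_held_out": self.n_inconclusive,
                "population_filtered": self.n_population_filtered,
            },
            "strategies": dict(self.strategy_labels),
            "warnings": list(self.warnings),
            "limitations": list(self.limitations),
        }
        if self.derived is not None:
            d = self.derived
            out["derived"] = {
                "youden": d.youden,
                "lr_positive": None if math.isinf(d.lr_positive) else d.lr_positive,
                "lr_positive_infinite": math.isinf(d.lr_positive),
                "lr_negative": None if math.isinf(d.lr_negative) else d.lr_negative,
                "lr_negative_infinite": math.isinf(d.lr_negative),
                "ppv": None if d.ppv is None or math.isnan(d.ppv) else d.ppv,
                "npv": None if d.npv is None or math.isnan(d.npv) else d.npv,
                "prevalence": d.prevalence,
                "flags": list(d.flags),
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def format_sweep_table(reports: dict[str, AccuracyReport]) -> str:
    """Aligned plain-text strategy-comparison table.

    One row per strategy label; per measure the without-IE, with-IE, and
    combined fractions followed by the percentage (two-decimal convention).
    """
    headers = [
        "Strategy",
        "Sens w/o IE",
        "Sens w/ IE",
        "Sens comb.",
        "Sensitivity",
        "Spec w/o IE",
        "Spec w/ IE",
        "Spec comb.",
        "Specificity",
    ]

    def cell(f: Optional[Fraction]) -> str:
        return "-" if f is None else f"{f[0]}/{f[1]}"

    rows = []
    for label, rep in reports.items():
        sens_bd = rep.breakdowns.get("sensitivity", {})
        spec_bd = rep.breakdowns.get("specificity", {})
        rows.append(
            [
                label,
                cell(sens_bd.get("without_ie")),
                cell(sens_bd.get("with_ie")),
                cell(sens_bd.get("combined")),
                format_percent(rep.measures["sensitivity"].estimate),
                cell(spec_bd.get("without_ie")),
                cell(spec_bd.get("with_ie")),
                cell(spec_bd.get("combined")),
                format_percent(rep.measures["specificity"].estimate),
            ]
        )
    widths = [
        max(len(headers[j]), *(len(r[j]) for r in rows)) if rows else len(headers[j])
        for j in range(len(headers))
    ]
    lines = [
        "  ".join(h.ljust(w) for h, w in zip(headers, widths)),
        "  ".join("-" * w for w in widths),
    ]
    for r in rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
    return "\n".join(lines)
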