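# diagest

Estimands and interfering-event strategies for diagnostic test accuracy
studies.

## The problem

A diagnostic accuracy study estimates how well an index test detects a
target condition, summarised by sensitivity
Se = P(T⁺ | D⁺) and specificity Sp = P(T⁻ | D⁻), with the true condition
classified by a reference standard. In practice the test conduct is
disturbed by **interfering events (IEs)** — coughing during a CT scan, a
panic attack in the MRI, early termination, hemolysed samples — that leave
an *affected* result, an *inconclusive* one, or no test decision at all
(a *non-existent* result, distinct from a value lost after collection).
The common habit of silently excluding such subjects changes the question
the study answers and can bias the estimates.

`diagest` makes the question explicit. An **estimand** is declared by five
attributes — population, target condition, index test (with its decision
rule), accuracy measure(s), and one handling strategy per anticipated IE —
and the engine turns that declaration plus subject-level data into an
accuracy report in which every exclusion, imputation, and alteration is
traceable to the attribute that produced it.

Six strategies are implemented. With I the index result and E the event
occurrence, the first three are *composite tests* g(I, E):

| strategy | decision when E occurred |
|---|---|
| diagnostic policy (DP) | the observed result I, event ignored |
| indicative event (IE±) | a fixed positive or negative result |
| setback (SB) | the opposite of the true condition (forced misclassification) |
| hypothetical (HY) | an imputed prediction of I had E not occurred |
| while under monitoring (WUM) | the decision from pre-event measurements only |
| principal stratum (PS1/PS2) | passthrough inside the target stratum, exclusion outside |

These definitions imply exact identities the test suite verifies on every
dataset: Se(SB) = Se(IE⁻), Sp(SB) = Sp(IE⁺), the ordering
Se(IE⁺) ≥ Se(DP) ≥ Se(SB) (and its specificity mirror), and DP accuracy is
the stratum-size-weighted average of the two principal-stratum accuracies.

The package also provides Wilson / Clopper–Pearson intervals, Youden index,
likelihood ratios and predictive values, a counts-only path for stratified
2×2×2 tables, a seeded synthetic-study simulator with counterfactual
results, and a comparative layer (paired/unpaired designs, difference /
ratio / odds contrasts with bootstrap CIs, four paired principal strata).

## Worked example

The package ships a notional 200-subject CT-scan study of suspected lung
carcinoma (40 diseased, 160 healthy) in which coughing interfered with 24
diseased and 40 healthy subjects. Comparing all strategies on one event
type:

```python
from diagest import format_sweep_table, strategy_sweep
from diagest.fixtures import ct_example_records

reports = strategy_sweep(ct_example_records(), "coughing")
print(format_sweep_table(reports))
```

```
Strategy  Sens w/o IE  Sens w/ IE  Sens comb.  Sensitivity  Spec w/o IE  Spec w/ IE  Spec comb.  Specificity
--------  -----------  ----------  ----------  -----------  -----------  ----------  ----------  -----------
DP        12/16        16/24       28/40       70%          110/120      34/40       144/160     90%
HY        12/16        18/24       30/40       75%          110/120      37/40       147/160     91.88%
WUM       12/16        12/24       24/40       60%          110/120      28/40       138/160     86.25%
PS1       12/16        -           12/16       75%          110/120      -           110/120     91.67%
PS2       -            16/24       16/24       66.67%       -            34/40       34/40       85%
IE+       12/16        24/24       36/40       90%          110/120      0/40        110/160     68.75%
IE-       12/16        0/24        12/40       30%          110/120      40/40       150/160     93.75%
SB        12/16        0/24        12/40       30%          110/120      0/40        110/160     68.75%
```

Same data, eight different estimands, sensitivities from 30% to 90%: the
choice of strategy *is* part of the clinical question. (Note the
hypothetical specificity is 147/160 = 91.88%; a 92.88% figure sometimes
quoted for this example contradicts its own cells — see
`docs/methods.md`.)

The estimator interface applies a declared estimand file (here: principal
stratum for arrhythmical breathing, indicative-positive for early
termination, hypothetical for claustrophobic seizures):

```python
from diagest import DiagnosticAccuracyEstimator
from diagest.fixtures import ct_example_records, load_ct_estimand

est = DiagnosticAccuracyEstimator(spec=load_ct_estimand())
est.fit(ct_example_records(event_type="arrhythmical_breathing"))
print(est.report_.measures["sensitivity"])   # 12/16 = 75% (95% CI 50.5%-89.82%)
print(est.report_.measures["specificity"])   # 110/120 = 91.67% (95% CI 85.34%-95.41%)
```

Sixty-four subjects are outside the event-free stratum; `est.audit_` lists
every one with the strategy that excluded it.

From a shell, the same analyses are `diagest estimate`, `diagest sweep`,
`diagest simulate`, `diagest compare`, and `diagest fixture` (which writes
the example CSV and estimand YAML shown above).

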