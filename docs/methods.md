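# Methods

## Scope and model

`diagest` operates on subject-level records of a diagnostic accuracy study:
a true condition (or a reference-standard result standing in for it), an
index test result in the vocabulary {positive, negative, inconclusive,
absent}, zero or more interfering-event (IE) occurrences with optional
times, and optionally a pre-event partial result and — for simulated data
only — a counterfactual result. Two states are kept strictly apart:
`inconclusive` is an existing result that classifies neither way
(intermediate values and uninterpretable administrations both map here,
distinguished by an optional subtype tag), while `absent` means no decision
exists. An `absent` result **with** an event occurrence is a non-existent
result caused by the event and is the business of the event's strategy; an
`absent` result **without** any occurrence models value loss unrelated to
any IE and is handled only by the engine's missing-data options
(`missing_index`: error, exclude with a bias warning, or a named imputer).

An estimand is declared by five attributes: population (free text plus an
optional pandas-query covariate filter), target condition, index test and
decision rule, an ordered list of accuracy measures, and a strategy map
assigning exactly one handling strategy to every anticipated event type.
Changing any attribute changes the estimand — the engine treats the
declaration as the unit of analysis and refuses data containing an occurred
event type the declaration does not cover.

## Strategies

Each strategy is a pure function from (record, event type, options) to a
decision with provenance. For a record whose governing event did not occur,
every strategy passes the observed result through; the one exception is
the principal-stratum strategy targeting the event-affected stratum, which
excludes unaffected records from the analysis set.

* **Diagnostic policy** uses the observed result regardless of the event.
  If the event left no decision, a configured imputer fills it; with no
  imputer this is an applicability error, because an event that always
  yields non-existent decisions cannot be handled by this strategy.
* **Indicative event** makes the event part of the decision rule: its
  occurrence yields the configured fixed positive or negative result, even
  when no observed result exists.
* **Setback** penalizes the event: the decision is set to the opposite of
  the true condition. It therefore needs the condition (or a reference
  imputer) for affected subjects.
* **Hypothetical** replaces affected results with a prediction of the
  result had the event not occurred, via a registered imputer. Built-ins:
  `constant:<result>`, `bernoulli:<p>` (seeded), and `oracle`, which reads
  the stored counterfactual and exists for simulation and validation; a
  covariate-model imputer is an extension point
  (`diagest.imputers.register_imputer`) because no canonical model form is
  fixed by the framework.
* **While under monitoring** uses only pre-event measurements: the stored
  partial result, or a registered `partial_rule` applied to the record.
  Post-event values are not "missing" under this estimand — they are
  outside the index test's observation window.
* **Principal stratum** restricts the analysis set to the stratum in which
  the event would (or would not) occur, with membership read from the
  observed occurrence.

One event governs each subject. When several occurred, `resolve_events`
picks the earliest (`first_event`; times required when two or more
occurred — a single occurred event is unambiguous and needs no time) or the
highest-priority type (`priority` with a declared total order). Ties raise
an error rather than being broken silently.

Diagnostic policy, indicative event, and setback form a composite-test
family: the decision is a truth-table function g(I, E) (plus the condition
for setback), exposed as `composite_decision` and verified exhaustively
against the record-level appliers.

Counts-only workflows on a 2×2×2 table (disease state × IE occurrence ×
result) are supported for every strategy that is a pure function of the
cells. The hypothetical and while-under-monitoring strategies are not; on
counts they require the corrected with-IE correct counts to be supplied
explicitly.

## Measures and intervals

Sensitivity and specificity are binomial proportions over non-excluded
subjects of the relevant condition. The default interval is the Wilson
score (well-behaved at boundary proportions, sensible at the small
denominators principal strata produce); Clopper–Pearson is available by
option. No interval method is canonical for this framework — this is the
package's choice. Interval bounds are clipped to [0, 1].

Inconclusive decisions default to a separately reported category; options
count them as positive, as negative, or exclude them — exclusion attaches a
warning because dropping inconclusive subjects restricts the analysed
spectrum and can bias both measures. Derived measures (Youden index,
likelihood ratios, predictive values at a supplied or empirical prevalence)
come from the point estimates; zero-cell likelihood ratios are reported as
infinity with a flag, with no continuity correction.

### A note on the worked example

The packaged CT example's hypothetical row has 110/120 correct without the
event and 37/40 with it, hence specificity 147/160 = 91.88% (91.875
rounded). A figure of 92.88% occasionally quoted for this example is
inconsistent with those cells and is treated as a transcription error; the
package reports the fraction-derived value.

## Engine

Pipeline order: population filter (the population is an estimand attribute,
so it is applied before anything else) → condition resolution → event
resolution → strategy application → missing/inconclusive handling →
measures. With `condition_source="reference"` the reference standard
classifies subjects (positive → diseased); inconclusive or absent
references are excluded with a warning or imputed by a seeded Bernoulli
draw at a supplied prevalence, and the report's limitations block records
that a reference standard, not the condition itself, was used. All
stochastic steps draw from a single `numpy` generator seeded by the
options; identical inputs and seed give byte-identical reports. The audit
log lists, per subject, the governing event, the strategy fired, the
provenance of the decision, and any imputation.

Declared imputation intents (`ImputationDirective(target, scope, imputer)`)
are validated against the estimand before fitting. Three combinations are
hard errors: imputing index results for event-affected subjects when an
event-free principal stratum is the target; imputing index results for
non-diseased subjects when sensitivity is requested; and imputing the
reference for index-positive subjects when PPV is requested (the
partial-verification setting). The scope vocabulary (all / diseased /
non_diseased / event_affected / event_free / index_positive /
index_negative) is this package's formalisation; the prohibitions
themselves are general.

The engine is packaged as a scikit-learn-style estimator
(`DiagnosticAccuracyEstimator`) so it composes with sklearn tooling;
`apply_estimand` is the equivalent function.

## Simulator

The generator draws, per subject: condition ~ Bernoulli(prevalence); a
counterfactual result from the baseline accuracies (sens0, spec0); an event
occurrence at a state-specific rate; if the event occurred, an observed
result from the degraded accuracies (sens_ie, spec_ie), an absent result
with probability `p_absent_given_ie`, and a partial result from
(partial_sens, partial_spec); otherwise the observed result equals the
counterfactual. The reference standard is perfect. Defaults are the worked
example's conditions: n = 200, prevalence 0.2, sens0 = 0.75,
spec0 = 110/120, event rates 0.6 / 0.25, sens_ie = 2/3, spec_ie = 0.85,
partial accuracies 0.5 / 0.7, and `p_absent_given_ie = 0` (the example's
with-event cells are fully observed). Closed-form targets per strategy
follow directly, e.g. DP sensitivity (1−r_d)·sens0 + r_d·sens_ie, oracle-HY
sens0, SB (1−r_d)·sens0; `strategy_recovery_experiment` checks the
Monte-Carlo estimates against them.

What the simulator does **not** emulate: imperfect or missing reference
standards (inject these by editing records), covariate-dependent event
mechanisms or covariate-model imputation, correlation between the partial
result and the final result beyond their shared dependence on the
condition, and event-unrelated value loss. Passing tests therefore show
that each strategy estimates its declared target under the stated
generative model, not that any strategy is unbiased for a particular real
study.

## Comparative designs

A paired study carries both tests' fields per subject; each arm may use its
own estimand (different strategies per test are explicitly supported).
Contrasts of sensitivity and specificity (difference, ratio, odds ratio)
take their intervals from a seeded bootstrap, default 2,000 resamples: a
nonparametric bootstrap over subjects for paired data (decisions are
computed once per arm and the subjects resampled, so stochastic imputers
stay fixed at their seeded values), or independent binomial resampling of
the two strata when only the two reports are available, which matches the
unpaired design's independence. The percentile interval is used; resamples
with an empty denominator or an infinite contrast are dropped from the
quantiles. A shared event type handled with the principal-stratum strategy
in both tests partitions a paired study into four strata (event in both /
neither / index only / comparator only) with per-stratum accuracies.
Stratum-membership prediction for unpaired designs is a documented,
unimplemented extension point: it needs a membership model no canonical
form is given for.

## Problem sizes in the test suite

The suite checks exact identities on 1,000 random tables, parameter
recovery at n = 10,000 with a pinned seed (3-binomial-SE bands), and
bootstrap coverage on 100 replicates of paired studies with n = 400 and 400
resamples each — sizes chosen so the full suite runs in seconds while the
Monte-Carlo bounds stay meaningful.
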