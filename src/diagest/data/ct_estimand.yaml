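# Estimand for the worked CT-scan example: accuracy (sensitivity and
# specificity) of a CT scan in detecting lung carcinoma among suspected
# patients aged 30 and above who can breathe rhythmically; early termination
# counts as a positive result; claustrophobic seizures are handled in a
# hypothetical scenario where they cannot occur.
spec_version: 1
population:
  description: >-
    Suspected lung-carcinoma cases aged 30 and above with at least two
    qualifying symptoms in the week before testing and a relevant exposure
    history.
  filter_query: null
target_condition:
  label: lung_carcinoma
  definition: >-
    At least one malignant lesion in the lung, restricted to the lung area.
index_test:
  rule: radiologist_reading
  description: >-
    Thorax and abdomen CT scan with contrast agent, evaluated by a
    radiologist who decides whether a tumour is present.
accuracy_measures:
  - sensitivity
  - specificity
strategy_map:
  arrhythmical_breathing:
    strategy: principal_stratum
    options:
      stratum: event_free
  early_termination:
    strategy: indicative_event
    options:
      fixed_result: positive
  claustrophobic_seizure:
    strategy: hypothetical
    options:
      imputer: oracle
multi_event_policy:
  policy: first_event
  priority: []
condition_source: true_condition
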