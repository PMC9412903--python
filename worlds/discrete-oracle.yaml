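kind: discrete
name: discrete-oracle
contexts:
- age: 82
  af_duration_months: 33
  resting_hr: 88
  bmi: 29
  heart_failure: 0
  la_enlargement: 0
  hypertension: 1
  symptomatic: 0
- age: 70
  af_duration_months: 70.2
  resting_hr: 88
  bmi: 29
  heart_failure: 0
  la_enlargement: 0
  hypertension: 0
  symptomatic: 1
- age: 70
  af_duration_months: 33
  resting_hr: 106
  bmi: 29
  heart_failure: 1
  la_enlargement: 0
  hypertension: 0
  symptomatic: 1
- age: 70
  af_duration_months: 33
  resting_hr: 88
  bmi: 35
  heart_failure: 0
  la_enlargement: 1
  hypertension: 0
  symptomatic: 1
probs:
- 0.25
- 0.25
- 0.25
- 0.25
outcome_rates:
- - - 0.002
    - 0.015
    - 0.02
  - - 0.004
    - 0.045
    - 0.09
  - - 0.004
    - 0.04
    - 0.07
  - - 0.004
    - 0.05
    - 0.045
- - - 0.002
    - 0.015
    - 0.09
  - - 0.002
    - 0.015
    - 0.02
  - - 0.004
    - 0.04
    - 0.07
  - - 0.004
    - 0.045
    - 0.05
- - - 0.004
    - 0.02
    - 0.11
  - - 0.004
    - 0.04
    - 0.09
  - - 0.004
    - 0.03
    - 0.08
  - - 0.002
    - 0.02
    - 0.015
- - - 0.004
    - 0.03
    - 0.1
  - - 0.004
    - 0.04
    - 0.08
  - - 0.002
    - 0.015
    - 0.03
  - - 0.004
    - 0.045
    - 0.07
expert_actions:
- RAC
- EXC
- AFA
- AAM
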