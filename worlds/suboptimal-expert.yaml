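kind: discrete
name: suboptimal-expert
contexts:
- age: 80
  af_duration_months: 48
  resting_hr: 75
  bmi: 30
  heart_failure: 1
  la_enlargement: 1
  hypertension: 1
  symptomatic: 0
- age: 45
  af_duration_months: 3
  resting_hr: 110
  bmi: 24
  heart_failure: 0
  la_enlargement: 0
  hypertension: 0
  symptomatic: 1
- age: 60
  af_duration_months: 12
  resting_hr: 95
  bmi: 28
  heart_failure: 0
  la_enlargement: 0
  hypertension: 1
  symptomatic: 1
- age: 55
  af_duration_months: 24
  resting_hr: 88
  bmi: 33
  heart_failure: 1
  la_enlargement: 0
  hypertension: 0
  symptomatic: 1
probs:
- 0.25
- 0.25
- 0.25
- 0.25
outcome_rates:
- - - 0.03
    - 0.1
    - 0.1
  - - 0.05
    - 0.4
    - 0.5
  - - 0.04
    - 0.3
    - 0.4
  - - 0.04
    - 0.5
    - 0.3
- - - 0.01
    - 0.1
    - 0.6
  - - 0.01
    - 0.1
    - 0.2
  - - 0.01
    - 0.2
    - 0.3
  - - 0.02
    - 0.3
    - 0.2
- - - 0.05
    - 0.2
    - 0.7
  - - 0.04
    - 0.3
    - 0.6
  - - 0.05
    - 0.3
    - 0.5
  - - 0.02
    - 0.2
    - 0.1
- - - 0.02
    - 0.15
    - 0.55
  - - 0.03
    - 0.2
    - 0.5
  - - 0.02
    - 0.2
    - 0.35
  - - 0.02
    - 0.25
    - 0.1
expert_actions:
- RAC
- EXC
- AAM
- AFA
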