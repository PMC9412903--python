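kind: continuous
name: default
age:
  mean: 68.0
  sd: 10.0
  lo: 35.0
  hi: 95.0
af_duration:
  mu: 3.1780538303479458
  sigma: 0.8
  hi: .inf
resting_hr:
  mean: 88.0
  sd: 15.0
  lo: 40.0
  hi: 180.0
bmi:
  mean: 29.0
  sd: 5.0
  lo: 16.0
  hi: 55.0
p_heart_failure: 0.3
p_la_enlargement: 0.4
p_hypertension: 0.6
p_symptomatic: 0.55
expert_weights:
- - 0.2
  - 1.0
  - 0.8
  - 0.2
  - 0.3
  - 0.5
  - 0.6
  - 0.2
  - -1.5
- - -0.5
  - -0.2
  - -1.0
  - 0.5
  - 0.0
  - 0.3
  - -0.3
  - 0.0
  - 1.0
- - 0.3
  - 0.1
  - -0.2
  - 0.0
  - -0.1
  - -0.5
  - 0.0
  - 0.1
  - 0.8
- - -0.3
  - -1.2
  - -0.5
  - 0.2
  - -0.2
  - 0.4
  - -0.8
  - -0.1
  - 1.2
outcome_logits:
- - - -3.4
    - 0.5
    - 0.0
    - 0.0
    - 0.0
    - 0.4
    - 0.0
    - 0.3
    - 0.0
  - - -3.4
    - 0.5
    - 0.0
    - 0.0
    - 0.0
    - 0.4
    - 0.0
    - 0.3
    - 0.0
  - - -3.4
    - 0.5
    - 0.0
    - 0.0
    - 0.0
    - 0.4
    - 0.0
    - 0.3
    - 0.0
  - - -3.4
    - 0.5
    - 0.0
    - 0.0
    - 0.0
    - 0.4
    - 0.0
    - 0.3
    - 0.0
- - - -1.8
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.6
    - 0.0
    - 0.0
    - 0.0
  - - -1.4
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.6
    - 0.0
    - 0.0
    - 0.0
  - - -1.5
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.6
    - 0.0
    - 0.0
    - 0.0
  - - -1.2
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.6
    - 0.0
    - 0.0
    - 0.0
- - - -0.1
    - 0.0
    - 0.3
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.5
  - - 0.2
    - 0.0
    - 0.3
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.5
  - - -0.4
    - 0.0
    - 0.3
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.5
  - - -1.3
    - 0.0
    - 0.3
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.0
    - 0.5
reference_scaler:
  means:
  - 68.0
  - 33.0
  - 88.0
  - 29.0
  sds:
  - 10.0
  - 31.0
  - 15.0
  - 5.0
expert_mode: argmax
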