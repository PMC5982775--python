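q: 0.02
n_families: 1600
gene: BRCA1
gamma: 0.3
seed: 1
max_age: 90
sister_dist:
  0: 0.1
  1: 0.25
  2: 0.3
  3: 0.2
  4: 0.1
  5: 0.05
daughter_dist:
  0: 0.55
  1: 0.25
  2: 0.15
  3: 0.05
breast_anchors:
  carrier:
  - - 25.0
    - 0.0
  - - 40.0
    - 0.1
  - - 50.0
    - 0.163
  - - 60.0
    - 0.305
  - - 70.0
    - 0.5
  noncarrier:
  - - 25.0
    - 0.0
  - - 40.0
    - 0.011
  - - 50.0
    - 0.063
  - - 60.0
    - 0.118
  - - 70.0
    - 0.16
ovarian_anchors:
  carrier:
  - - 30.0
    - 0.0
  - - 50.0
    - 0.05
  - - 60.0
    - 0.137
  - - 70.0
    - 0.215
  noncarrier:
  - - 30.0
    - 0.0
  - - 50.0
    - 0.004
  - - 60.0
    - 0.007
  - - 70.0
    - 0.014
followup_age:
  proband:
  - 52.0
  - 10.0
  mother:
  - 68.0
  - 10.0
  sister:
  - 52.0
  - 12.0
  daughter:
  - 30.0
  - 10.0
p_rrso: 0.03
rrso_age_range:
- 35
- 60
p_rrm: 0.01
rrm_age_range:
- 30
- 55
p_dead: 0.1
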