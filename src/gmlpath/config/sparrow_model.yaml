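nodes:
- name: year
  family: categorical-exogenous
  table: nestlings
- name: timing
  family: gaussian
  grouping:
  - nest
  table: nestlings
- name: fledglings
  family: gaussian
  grouping:
  - nest
  table: nestlings
- name: tarsus_nest
  family: gaussian
  grouping:
  - nest
  table: nestlings
- name: nestling_mass
  family: gaussian
  grouping:
  - nest
  table: nestlings
- name: date
  family: gaussian
  grouping:
  - nest
  - individual
  table: captures
- name: time_captured
  family: gaussian
  grouping:
  - nest
  - individual
  table: captures
- name: tarsus_adult
  family: gaussian
  grouping:
  - nest
  - individual
  table: captures
- name: moult
  family: ordinal-as-numeric
  grouping:
  - nest
  - individual
  table: captures
- name: tbw
  family: gaussian
  grouping:
  - nest
  - individual
  table: captures
- name: fat
  family: gaussian
  grouping:
  - nest
  - individual
  table: captures
edges:
- from: timing
  to: fledglings
  form: linear
- from: fledglings
  to: nestling_mass
  form: linear
- from: timing
  to: nestling_mass
  form: linear
- from: tarsus_nest
  to: nestling_mass
  form: linear
- from: fledglings
  to: tarsus_nest
  form: linear
- from: timing
  to: tarsus_nest
  form: linear
- from: tarsus_nest
  to: tarsus_adult
  form: linear
- from: timing
  to: moult
  form: linear
- from: date
  to: moult
  form: linear
- from: nestling_mass
  to: tbw
  form: linear
- from: moult
  to: tbw
  form: quadratic
- from: timing
  to: tbw
  form: linear
- from: date
  to: tbw
  form: linear
- from: time_captured
  to: tbw
  form: linear
- from: tarsus_adult
  to: tbw
  form: linear
- from: date
  to: tbw
  form: interaction
  with: timing
- from: nestling_mass
  to: fat
  form: linear
- from: timing
  to: fat
  form: linear
- from: moult
  to: fat
  form: linear
- from: date
  to: fat
  form: linear
- from: time_captured
  to: fat
  form: linear
- from: tarsus_adult
  to: fat
  form: linear
- from: year
  to: timing
  form: linear
- from: year
  to: fledglings
  form: linear
- from: year
  to: nestling_mass
  form: linear
- from: year
  to: tarsus_nest
  form: linear
- from: year
  to: moult
  form: linear
- from: year
  to: tbw
  form: linear
- from: year
  to: fat
  form: linear
free_covariance:
- - fat
  - tbw
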