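scenario_id: global_2
populations:
- name: nana
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
- name: svalbard
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
- name: exilis
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
- name: admixed
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
- name: gland_w
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
- name: gland_e
  sampled: true
  n_diploids: 20
  ne:
    dist: uniform
    lower: 100
    upper: 100000
events:
- id: div_sval
  kind: divergence
  time:
    dist: loguniform
    lower: 50
    upper: 2000
  derived: svalbard
  ancestor: nana
- id: div_admx
  kind: divergence
  time:
    dist: loguniform
    lower: 500
    upper: 10000
  derived: admixed
  ancestor: gland_w
- id: div_nana
  kind: divergence
  time:
    dist: loguniform
    lower: 20000
    upper: 150000
  derived: nana
  ancestor: exilis
- id: div_we
  kind: divergence
  time:
    dist: loguniform
    lower: 15000
    upper: 120000
  derived: gland_w
  ancestor: gland_e
- id: div_gland
  kind: divergence
  time:
    dist: loguniform
    lower: 30000
    upper: 200000
  derived: gland_e
  ancestor: exilis
constraints:
- t_div_nana > t_div_sval
- t_div_we > t_div_admx
- t_div_gland > t_div_we
- t_div_gland > t_div_nana
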