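scenario_id: global_4
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
- name: tundrarum
  sampled: false
  n_diploids: 0
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
- id: intro_tn
  kind: introgression
  time:
    dist: loguniform
    lower: 300
    upper: 5000
  recipient: nana
  donor: tundrarum
  rate:
    dist: uniform
    lower: 0.01
    upper: 0.99
- id: div_admx
  kind: divergence
  time:
    dist: loguniform
    lower: 500
    upper: 10000
  derived: admixed
  ancestor: gland_w
- id: intro_gland
  kind: introgression
  time:
    dist: loguniform
    lower: 2000
    upper: 30000
  recipient: gland_w
  donor: gland_e
  rate:
    dist: uniform
    lower: 0.01
    upper: 0.99
- id: adm_tund
  kind: admixture
  time:
    dist: loguniform
    lower: 5000
    upper: 50000
  admixed: tundrarum
  source1: exilis
  source2: nana
  rate:
    dist: uniform
    lower: 0.01
    upper: 0.99
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
- t_intro_tn > t_div_sval
- t_adm_tund > t_intro_tn
- t_div_nana > t_adm_tund
- t_div_we > t_div_admx
- t_div_we > t_intro_gland
- t_div_gland > t_div_we
- t_div_gland > t_div_nana
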