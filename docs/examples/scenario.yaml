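name: two_sample_branching
clones:
- clone_id: C0
  parent_id: null
  n_private_mutations: 200
  per_sample_ccf:
    a: 1.0
    b: 1.0
  marker_gene: null
- clone_id: C1
  parent_id: C0
  n_private_mutations: 150
  per_sample_ccf:
    a: 1.0
    b: 0.0
  marker_gene: null
- clone_id: C2
  parent_id: C0
  n_private_mutations: 180
  per_sample_ccf:
    a: 0.0
    b: 1.0
  marker_gene: null
samples:
- sample_id: a
  purity: 0.7
  mean_depth: 150.0
  cn_profile:
  - - '1'
    - 1
    - 10000000
    - 2
- sample_id: b
  purity: 0.7
  mean_depth: 150.0
  cn_profile:
  - - '1'
    - 1
    - 10000000
    - 2
seed: 0
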