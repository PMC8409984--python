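seed: 1
simulate:
  n_genes: 400
  n_modules_planted: 5
  module_size: 30
  marker_genes_per_region: 3
  noise_sd: 0.2
  lists:
    - {name: homeostatic_list, size: 15, target_group: homeostatic, strength: 1.0}
    - {name: executive_list, size: 15, target_group: executive, strength: 1.0}
    - {name: background_list, size: 15, target_group: homeostatic, strength: 0.0}
frequency:
  q: 0.05
  include_mesc: true
gsea:
  level: group
  n_perm: 1000
  q: 0.05
modules:
  method: wgcna
  min_module_size: 3
  cut_fraction: 0.95
overrep:
  formula: paper
  include_unassigned: false
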