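# "LSH-rescue" simulation preset: a wild-type reference, an empty-vector
# null baseline, one efficient rescue (LSH-like, rho 0.6, gene bodies
# recovering slightly better than intergenic regions) and one weak rescue
# (K237Q-like, rho 0.1, intergenic recovering better than gene bodies).
n_regions:
  promoter: 300
  gene_body: 300
  intergenic: 300
  "repeat:IAP": 120
  "repeat:LINE": 120
  "repeat:minor_satellite": 60
  "repeat:major_satellite": 60
region_length:
  promoter: [500, 2000]
  gene_body: [2000, 20000]
  intergenic: [1000, 10000]
  "repeat:IAP": [2000, 7000]
  "repeat:LINE": [1000, 6000]
  "repeat:minor_satellite": [300, 2000]
  "repeat:major_satellite": [500, 5000]
fraction_lsh_dependent:
  promoter: 0.20
  gene_body: 0.40
  intergenic: 0.40
  default: 0.90
wt_methylation: [0.55, 0.95]
invariant_methylation: [0.05, 0.95]
region_effect_log2_range: [0.0, 6.0]
loss_fraction: 0.95
samples:
  - id: WT
    role: reference
    label: wild-type MEF
  - id: MSCV
    role: baseline
    label: Lsh-/- empty vector
  - id: LSH
    role: test
    label: Lsh-/- + wild-type LSH
    rho: 0.6
    class_bias:
      gene_body: 1.15
      intergenic: 0.85
  - id: K237Q
    role: test
    label: Lsh-/- + ATPase-dead K237Q
    rho: 0.1
    class_bias:
      intergenic: 1.6
      gene_body: 0.6
depth: 200.0
dispersion: 0.2
background: 0.05
n_invariant: 300
library_factor_range: [0.5, 2.0]
bisulfite:
  n_clones: 50
  conversion_failure: 0.02
  seq_error: 0.002
assays:
  qpcr_ct_sd: 0.1
  hplc_area_sigma: 0.02
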