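# Fully-specified default run configuration.  Every named constant of the
# workflow appears here exactly once.
seed: 17
out_dir: netmark_run

simulate:
  enabled: true
  n_nodes: 2000
  attachment_m: 2
  module_size: 25
  signal_mean: 3.0
  n_biomarkers: 16
  biomarker_placement: hub      # 'hub' or 'random'
  n_cases: 275
  n_controls: 349
  noise_sd: 1.0
  biomarker_auc_target: 0.9     # binormal AUC of biomarker genes
  module_auc_target: 0.75       # binormal AUC of other module genes

inputs:                          # used when simulate.enabled is false
  network: null                  # edge-list TSV
  de_table: null                 # gene/log2fc/pvalue TSV
  expression: null               # genes x samples TSV
  labels: null                   # sample/group TSV
  biomarkers: null               # known-biomarker gene list (one per line)
  truth: null                    # planted-truth JSON (synthetic reruns)

network:
  min_confidence: 0.7            # keep edges with confidence strictly above

diffexpr:
  p_threshold: 0.05              # DEG filter: pvalue strictly below
  lfc_threshold: 1.0             # DEG filter: |log2FC| strictly above

module:
  enabled: true
  iterations: 10                 # greedy restarts from the top-z seed nodes
  max_size: 30
  normalization: stouffer        # 'stouffer' (1/sqrt k) or 'mean' (1/k)
  z_threshold: 1.0               # genes above this z seed the CCS subnetwork
  membership: null               # user-supplied module TSV when enabled: false

select:
  min_split: 20
  complexity: 0.01
  flavor: classification         # 'classification' or 'regression'

train:
  kernel: bessel
  sigma: 1.0
  degree: 1
  nu: 1.0
  scale: 1.0
  offset: 1.0
  C: 1.0
  train_fraction: 0.7
  compare_kernels: true

predict:
  cutoff: 0.99                   # SVM-point probability cutoff for candidates
  universe: ccs                  # score all subnetwork nodes ("ccs") or only DEGs ("degs")

evaluate:
  panel: true
  top_genes: 5                   # single-gene ROC reported for the top-ranked genes
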