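# Example pipeline configuration (all values shown are the defaults).
seed: 0
use_default_study: true   # simulate the built-in synthetic study
k_override: null          # set to force a specific top-K at any scale

preprocess:
  max_zero_fraction: 0.5  # remove features with more than 50% zero counts
  min_mean: 10.0          # remove features with mean count below 10
  annotation_filter_genes: true
  annotation_filter_mirs: false

de:
  gene_lfc: 1.0           # genes: |log2FC| > 1.0
  gene_p: 1.0e-5          #        BH-adjusted p < 1e-5
  gene_use_adjusted: true
  mir_lfc: 0.5            # miRs:  |log2FC| > 0.5
  mir_p: 1.0e-5           #        raw p < 1e-5
  mir_use_adjusted: false
  dispersion_mode: moments  # or "shrink" (50/50 toward a fitted trend)
  pseudocount: 0.5

network:
  k: 100000               # study-scale top-K (the default synthetic study
                          # uses the proportional K = 336 unless overridden)
  n_bins: auto            # max(2, floor(n_samples^(1/3)))
  bias_correction: false  # Miller-Madow term
  rank_transform: true

compare:
  level: topk             # or "canonical"
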