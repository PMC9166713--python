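# Example configuration for `lectiscope run`: a small synthetic study with
# planted lectins across five body sites plus a glycan-array screen.
seed: 17
synthetic:
  universe:
    n_true_lectins: 20
    n_decoys: 20
  catalogs:
    sites:
      - {name: stool, n_samples: 10, p_inclusion: 0.5}
      - {name: buccal_mucosa, n_samples: 10, p_inclusion: 0.3}
      - {name: supragingival_plaque, n_samples: 10, p_inclusion: 0.3}
      - {name: tongue_dorsum, n_samples: 10, p_inclusion: 0.3}
      - {name: posterior_fornix, n_samples: 10, p_inclusion: 0.1}
    n_background: 2
  array:
    n_binders: 8
    n_nonbinders: 8
    noise_sd: 400.0
    outlier_prob: 0.1
pipeline:
  cluster_threshold: 0.90
  match_threshold: 0.90
  min_coverage: 0.8
  binder_threshold: 0.1
  max_motif_size: 4
  top_fraction: 0.1
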