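{
  "seed": 7,
  "stages": ["generate", "preprocess", "fit", "recover", "growth", "outcomes"],
  "generator": {
    "n_cohort": 3714,
    "n_subsample": 187
  },
  "sampler": {"n_chains": 3, "n_warmup": 2000, "n_draws": 2000},
  "recovery": {"n_sets": 50, "n_trials": 100},
  "mediation_boot": 10000
}
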