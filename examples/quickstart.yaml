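# Small demonstration cohort: completes end-to-end in well under a minute.
# The planted effect is larger than the package default so the
# filter -> consensus funnel stays populated at this reduced sample size.
seed: 1
simulate:
  shared:
    n_proteins: 200
    n_informative: 7
    effect_size: 0.7
    cirrhosis_leak: 0.3
  test:
    n_hcc: 60
    n_cirrhotic: 30
    n_healthy: 60
  validation:
    n_hcc: 40
    n_cirrhotic: 20
    n_healthy: 40
committee:
  n_repeats: 5
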