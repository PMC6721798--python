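# Demo pipeline configuration: reproduces the published analysis conditions
# on synthetic data (printed fold changes and SDs; k_off = 0.006 min^-1).
outdir: results/demo
seed: 2019
n_draws: 100000
reporter:
  mode: fold_override
  fold_targets: {DPAR: 38.0, D3RE: 6.0, LOOP: 12.5, DOUBLE: 41.8}
  n: 100
  cv: 0.10
emsa:
  koff: 0.006
  dissociation_fold: 100000
  dose_folds: [1000, 2000, 4000, 8000, 16000, 32000, 64000, 100000]
  noise_sd: 0.02
variants: [G51C, G52C, A15G, G16C]
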