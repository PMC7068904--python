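# Planted-optimum study: the analytic bowl with seeded 2%-of-base noise.
# Run:  tkaopt run --config examples/planted_study.yaml --out results/planted --seed 1
evaluator: planted
seed: 1
planted:
  base_mpa: 16.4
  optimum_deg: [0.0, 1.0, 4.0]
  weights_mpa_per_deg2: [0.9, 0.7, 0.6]
  noise_sd_mpa: 0.328
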