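# Full screening with the elastic-foundation surrogate as the evaluator.
# Omitted blocks take the documented defaults (L9 factors, 1150 N load,
# polyethylene liner 685 MPa / nu 0.4 / 9 mm, default ligaments).
# Run:  tkaopt run --config examples/surrogate_study.yaml --out results/surrogate
evaluator: surrogate
precision: 2
surrogate:
  geometry:
    grid_spacing_mm: 0.5
  load:
    axial_force_n: 1150.0
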