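# Example study configuration for the plaquemech CLI, e.g.
#   plaquemech generate --config examples/study.yaml --out vessel.vtu
#   plaquemech recover  --config examples/study.yaml --out report.json
geometry:
  dim: 2
  inner_radius: 1.5      # mm
  wall_thickness: 1.0    # mm
  n_circ: 24
  n_rad: 4
  inclusions:
    - {tissue: fibrous, theta: [0.0, 70.0]}
    - {tissue: lipid,   theta: [90.0, 183.6], radial: [0.25, 0.75]}
    - {tissue: mixed,   theta: [210.0, 231.0], radial: [0.25, 0.75]}
    - {tissue: calcium, theta: [240.0, 247.5], radial: [0.3333, 0.5]}
model: linear                 # linear | yeoh | yeoh-calcium
objective_mode: interface     # interface | surface | diameter
load: {p_base_mmhg: 0.0, p_target_mmhg: 60.0}
optimizer:
  population: 24
  generations: 7
  sqp_max_evals: 40
  sqp_residual: 1.0e-9
seeds: [1, 2, 3]
# noise: {n: 0.05}            # uncomment for a displacement-noise study
# pressure_perturbation: 0.05 # target generated at a perturbed pressure
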