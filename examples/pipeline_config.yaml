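# Small full-pipeline configuration for `septalflow run-all`.
# All lengths in voxels; omitted keys fall back to package defaults
# (48^3 phantom, pressure-ladder inlets, omega_f=1.0, omega_g=1.6).
phantom:
  shape: [32, 32, 32]
  chamber_semi_axes: [8, 10, 10]
  chamber_offset: 7
  orifice_radius: 2
  port_radius: 3
render:
  lumen_intensity: 0.9
  tissue_intensity: 0.1
  blur_sigma: 1.0
  noise_sigma: 0.05
segmentation:
  c1: 1.0
  c2: 0.7
simulation:
  omega_f: 1.0
  omega_g: 1.6
  max_steps: 1500
seed: 5
simulate_on: ground_truth
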