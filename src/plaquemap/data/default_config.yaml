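# Default pipeline configuration: 12 synthetic plaques, the measured
# per-class T1/T2* distributions, and the two acquisition protocols
# (VFA: TR 10 ms, FA 5/10/20/30/40 deg; multi-echo: TR 22 ms, TE 4-20 ms).
# Nine plaques carry all four tissue classes; two are predominantly fibrous
# (QDA not applicable there) and one has only fibrous tissue and lipids.

seed: 20210117

classes: default

phantoms:
  - {plaque_id: plaque01, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque02, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque03, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque04, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque05, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque06, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque07, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque08, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque09, grid_shape: [4, 44, 44]}
  - {plaque_id: plaque10, grid_shape: [4, 44, 44], classes_present: [fibrous]}
  - {plaque_id: plaque11, grid_shape: [4, 44, 44], classes_present: [fibrous]}
  - {plaque_id: plaque12, grid_shape: [4, 44, 44], classes_present: [fibrous, lipid]}

protocols:
  vfa:
    tr: 10.0
    flip_angles: [5, 10, 20, 30, 40]
    te_fixed: 2.0
    noise_model: rician
    noise_sigma: 0.005
  multiecho:
    tr: 22.0
    echo_times: [4, 8, 12, 16, 20]
    flip_angle: 10.0
    noise_model: rician
    noise_sigma: 0.005

roi_sampling:
  n_per_class: {fibrous: 18, lipid: 12, inflammation: 9, hemorrhage: 7}
  size_range: [4, 9]

qda:
  scope: per_plaque
  shrinkage: 0.1
  priors: empirical
  ci_level: 0.95
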