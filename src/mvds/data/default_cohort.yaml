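n_patients: 56
prop_supratentorial: 0.6785714285714286
severity_mean: 0.24214751314286345
severity_sd: 1.0
item_noise_sd: 1.0
item_thresholds:
  lip_closure:
  - 2.2859862387440137
  mastication:
  - 0.5182941298829763
  oral_transit_time:
  - 1.5088776696532453
  triggering_pharyngeal_swallow:
  - -2.9982341368365946
  epiglottis_inversion:
  - 2.5624286474981255
  valleculae_residue:
  - -1.8123876048736465
  - 1.1902321628999897
  - 1.9870712566946092
  pyriformis_residue:
  - 0.10644765981953207
  - 1.592957611223415
  - 2.4758439854224896
  pharyngeal_wall_coating:
  - 1.210561132020674
  aspiration:
  - -1.4657381559184341
  - 0.741614317187116
rater_noise: 0.11
beta_feeding: -0.114
beta_pneumonia: 0.051
intercept_feeding: 5.957041130294572
intercept_pneumonia: -3.1495781342207305
prop_male: 0.5892857142857143
seed: 0
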