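# Per-compartment electrical conductivities, S/m.
# Head (mm) scale, capillary voxel (um) scale, and BBB ultrastructure (nm)
# scale compartments share one table; override entries per run if needed.
conductivities:
  scalp: 0.465
  fat: 0.025
  skull: 0.01
  csf: 0.8
  gray_matter: 0.276
  white_matter: 0.126
  electrode: 5.9e+7
  parenchyma: 0.276
  lumen: 0.7
  cleft_channel: 1.5
  astrocytic_channel: 1.5
  glycocalyx: 0.3
  basement_membrane: 0.3
  insulating_membrane: 1.0e-5
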