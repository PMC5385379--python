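cine_matrix:
- 128
- 128
- 15
groups:
  MNA_6m:
    dilation_factor: 1.045
    n_animals: 7
    n_leak: 6
  Perindopril_6m:
    dilation_factor: 1.055
    n_animals: 9
    n_leak: 6
  Untreated_6m:
    dilation_factor: 0.9282
    n_animals: 8
    n_leak: 15
npx50_threshold: 0.5
output_dir: endoprofile_out
rim_thickness_px: 2
seed: 1
segmentation_fraction: 0.5
snr: 30.0
vessel_radius_mm: 1.25
vfa_matrix:
- 96
- 80
- 4
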