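# Minutes-scale smoke experiment: tiny chips, 2 folds, 3 epochs.
seed: 0
chips_per_level: 2
level0_missing_rois: 0
epochs: 3
generator:
  roi_height_px: 48
  roi_width_px: 48
  n_rois_per_chip: 4
  n_slices: 3
preprocess:
  slice_selection: [1, 2, 3]
cv:
  folds: 2
schedule:
  kind: step
  alpha0: 0.001
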