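# Full-scale study conditions: 6 chips per level, 16 ROIs, 27-slice stacks,
# 7 selected slices, 2 missing level-0 ROI stacks (658/672/672/672 images;
# train 2,004 / validation 222 / test 448), 10-fold cross-validation with the
# step-decay schedule that performed best.
seed: 0
chips_per_level: 6
level0_missing_rois: 2
epochs: 50
generator: {}          # defaults: 96x96 ROIs, 16 per chip, 27 slices
preprocess:
  slice_selection: [1, 3, 5, 14, 23, 25, 27]
  val_fraction: 0.10
cv:
  folds: 10
adam:
  batch_size: 32
schedule:
  kind: step
  alpha0: 0.001
  eta: 2.0
  gamma: 5.0
augment:
  vertical_flip: true
  zoom_low: 0.1
  zoom_high: 0.2
  shift_low: -0.05
  shift_high: 0.05
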