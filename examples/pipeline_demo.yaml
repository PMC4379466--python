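# Demo: full simulate -> localize -> quality -> resolution -> render -> register
# run on a pair of parallel membranes 300 nm apart in a 2.56 x 2.56 um field.
seed: 7
field_of_view_nm: [2560.0, 2560.0]
structure:
  kind: membrane_pair
  spacing: 300.0
  length: 2000.0
  density_per_um: 800.0
  angle_deg: 0.0
switching:
  recovery_rate: 0.02
  bleach_prob: 0.3
camera:
  em_gain: 30.0
  read_noise: 20.0
movie:
  n_frames: 300
  shape_px: [32, 32]
  background: 5.0
quality:
  n_epochs: 2
  search_radius_nm: 200.0
resolution:
  K: 20
render:
  out_pixel: 10.0
register:
  kind: similarity
  transform:
    scale: 0.1
    rotation_deg: 15.0
    translation_px: [20.0, 10.0]
  em_size_px: [320, 320]
  noise_level: 0.02
  alpha: 0.5
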