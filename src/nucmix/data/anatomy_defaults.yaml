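n_subjects: 30
seed: 0
spacing: 0.5
margin_mm: 15.0
stn_volume_mean: 119.88
stn_volume_sd: 20.0
sn_volume_mean: 450.0
sn_volume_sd: 60.0
com_separation_left: 6.4
com_separation_right: 6.7
stn_center_left:
- -10.5
- -13.5
- -6.0
separation_direction_left:
- 0.15
- -0.3
- -0.94
stn_axis_ratio:
- 2.0
- 1.5
- 1.0
sn_axis_ratio:
- 2.5
- 1.0
- 1.7
sn_tilt_deg: 0.0
sn_pitch_deg: 35.0
center_jitter_sd: 1.0
relative_jitter_sd: 0.3
rotation_jitter_sd: 6.0
erosion_prob: 0.5
erosion_compensation_mm: 0.42
carve_max_fraction: 0.05
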