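mode: ontogenetic
stage: onto4y
target_total_mass: 16.5
per_segment_length_ratio: {torso: 0.62, pelvis: 0.58, thigh_l: 0.52, thigh_r: 0.52,
  shank_l: 0.52, shank_r: 0.52, foot_l: 0.58, foot_r: 0.58}
mass_fraction_table: {torso: 0.585, pelvis: 0.145, thigh_l: 0.082, thigh_r: 0.082,
  shank_l: 0.04, shank_r: 0.04, foot_l: 0.013, foot_r: 0.013}
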