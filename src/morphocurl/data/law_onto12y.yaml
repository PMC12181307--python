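mode: ontogenetic
stage: onto12y
target_total_mass: 40.0
per_segment_length_ratio: {torso: 0.84, pelvis: 0.8, thigh_l: 0.81, thigh_r: 0.81,
  shank_l: 0.81, shank_r: 0.81, foot_l: 0.82, foot_r: 0.82}
mass_fraction_table: {torso: 0.555, pelvis: 0.143, thigh_l: 0.094, thigh_r: 0.094,
  shank_l: 0.044, shank_r: 0.044, foot_l: 0.013, foot_r: 0.013}
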