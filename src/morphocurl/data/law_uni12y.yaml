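{mode: uniform, stage: uni12y, height_ratio: 0.828, target_total_mass: 40.0}
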