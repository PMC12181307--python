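{mode: uniform, stage: uni4y, height_ratio: 0.572, target_total_mass: 16.5}
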