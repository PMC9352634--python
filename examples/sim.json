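{"scene": {"fov_shape": [48, 48], "n_rois": 3, "seed": 4},
 "motion": {"drift_sd": 0.0}, "duration_s": 25.0, "rate_hz": 20.0}
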