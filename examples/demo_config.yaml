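# Demo pipeline configuration: full study design, default noise and hazards.
seed: 11
outdir: run_out
n_per_gender: 10
noise_cv: 0.05
cap_per_arm: 5
press_mode: printed
ratio_mode: ratio-of-means
mpress_m: 3
compute_press: true
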