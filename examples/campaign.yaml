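# Reduced sensor-A campaign: two placements, five repeated trials each.
# Run with:  mwicp run --config examples/campaign.yaml --out runs/demo
sensors: [A]
placements: ["20mm", "10mm"]
n_repeats: 5
duration_s: 40.0
f_th_mhz: 50.0
oss_threshold: 0.8
alpha: 0.001
cv_folds: 5
seed: 123
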