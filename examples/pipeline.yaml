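# Demo end-to-end pipeline configuration: simulate a small cohort and a
# handful of plates, call clonality, profile copy number, fit dose
# response and run the null simulation.
out_dir: scratch/demo_run
n_patients: 5
n_plates: 8
cn_noise_sd: 0.1
seed_simulate: 11
seed_associate: 12
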