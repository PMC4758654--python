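# Full coupled model with the reference Dll4 exclusion distance (80).
mode: vascular
t_end_days: 5.1
seed: 0
nx: 512
ny: 396
output_every_days: 0.1
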