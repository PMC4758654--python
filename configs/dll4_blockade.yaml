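# Down-regulated Delta/Notch signaling: tip cells may activate closer together.
mode: dll4_blockade
delta4_override: 55.0
t_end_days: 5.1
seed: 0
nx: 512
ny: 396
output_every_days: 0.1
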