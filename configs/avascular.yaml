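# Angiogenesis blocked: capillary and TAF dynamics frozen, no tip cells, S = 1.
mode: avascular
t_end_days: 1054.0
seed: 0
nx: 512
ny: 396
output_every_days: 2.0
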